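"""Synthetic allotetraploid genomes, meioses, hybrids, read counts, phenotypes.

The generator emulates a tetrazyg rootstock cross: two doubled-diploid
parents, each carrying two *identical pairs* of divergent homologs, produce
diploid gametes through bivalent-only meiosis with per-chromosome
preferential pairing, and their union gives tetraploid hybrids genotyped by
read counts over ancestor-diagnostic SNPs.

Ancestry along every chromatid is represented as a piecewise-constant track
``[(end_bp, ancestor), ...]`` with an implicit start at the previous end (or
zero).  Crossovers are tail swaps between one chromatid of each pairing
partner, so ancestry tracks stay exact at base-pair resolution and the
ground truth (pairing configuration, crossover positions, gamete
haplotypes) is retained for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# The four ancestral taxa of the Volkamer lemon x Swingle citrumelo cross.
RETICULATA = "reticulata"
MEDICA = "medica"
MAXIMA = "maxima"
TRIFOLIATA = "trifoliata"
ANCESTORS = (RETICULATA, MEDICA, MAXIMA, TRIFOLIATA)

HOMOLOGOUS = "homologous"
HETEROLOGOUS = "heterologous"

#: ancestry track: list of (segment end in bp, ancestor label); implicit
#: start of segment i is the end of segment i-1 (0 for the first).
Track = list[tuple[float, str]]


# ---------------------------------------------------------------------------
# genome and parents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Reference coordinate frame: chromosome sizes, centromeres, map lengths.

    ``map_lengths`` are expected genetic lengths in Morgans per chromosome
    (crossovers per bivalent are drawn with mean twice this value, so the
    transmitted chromatid carries the stated map length on average).
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, float]
    map_lengths: dict[str, float]

    def __post_init__(self) -> None:
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            cen = self.centromeres[name]
            if not 0 < cen < length:
                raise ValueError(f"centromere of {name} outside (0, {length})")
            if self.map_lengths[name] < 0:
                raise ValueError(f"negative map length for {name}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def centromere_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.names,
             "centromere": [self.centromeres[c] for c in self.names]}
        )


def default_genome(n_chromosomes: int = 9, chrom_length: int = 20_000_000,
                   map_length: float = 1.0,
                   centromere_frac: float = 0.45) -> GenomeSpec:
    """Nine-chromosome desk-scale frame standing in for the citrus reference."""
    chroms = tuple((f"C{i + 1}", int(chrom_length)) for i in range(n_chromosomes))
    names = [c for c, _ in chroms]
    return GenomeSpec(
        chromosomes=chroms,
        centromeres={c: centromere_frac * chrom_length for c in names},
        map_lengths={c: float(map_length) for c in names},
    )


@dataclass
class ParentKaryotype:
    """Doubled-diploid parent: two distinct homolog ancestry tracks per
    chromosome, each present in two identical copies."""

    name: str
    haplotypes: dict[str, tuple[Track, Track]]

    def __post_init__(self) -> None:
        for chrom, (h1, h2) in self.haplotypes.items():
            for track in (h1, h2):
                _validate_track(track, chrom)

    def ancestor_dose(self, chrom: str, positions: np.ndarray,
                      ancestor: str) -> np.ndarray:
        """Somatic dose (0-4) of ``ancestor`` at ``positions``; each distinct
        homolog counts twice (doubled diploid)."""
        h1, h2 = self.haplotypes[chrom]
        return 2 * (track_labels_at(h1, positions) == ancestor).astype(int) \
            + 2 * (track_labels_at(h2, positions) == ancestor).astype(int)


def _validate_track(track: Track, chrom: str = "?") -> None:
    if not track:
        raise ValueError(f"empty ancestry track on {chrom}")
    prev = 0.0
    for end, label in track:
        if label not in ANCESTORS:
            raise ValueError(f"unknown ancestor label {label!r}")
        if end <= prev:
            raise ValueError(f"non-increasing segment end {end} on {chrom}")
        prev = end


def _normalize(track: Track) -> Track:
    """Merge adjacent segments with the same label."""
    out: Track = []
    for end, label in track:
        if out and out[-1][1] == label:
            out[-1] = (end, label)
        else:
            out.append((end, label))
    return out


def track_labels_at(track: Track, positions: np.ndarray) -> np.ndarray:
    """Ancestor label of ``track`` at each position (positions in (0, L])."""
    ends = np.array([e for e, _ in track])
    labels = np.array([lab for _, lab in track], dtype=object)
    idx = np.searchsorted(ends, np.asarray(positions, dtype=float), side="left")
    return labels[np.minimum(idx, len(labels) - 1)]


def build_parent_karyotypes(
    genome: GenomeSpec,
    citrumelo_breakpoints: dict[str, list[float]] | None = None,
) -> tuple[ParentKaryotype, ParentKaryotype]:
    """Build the two tetraploid parents of the cross.

    Volkamer lemon is heterozygous C. reticulata / C. medica along the whole
    genome; Swingle citrumelo carries one P. trifoliata homolog and one
    mosaic homolog alternating C. reticulata / C. maxima.  By default the
    mosaic switches once at mid-chromosome, the starting taxon alternating
    with chromosome parity; pass explicit per-chromosome breakpoints to
    override (an empty list makes the homolog single-ancestor).
    """
    volk: dict[str, tuple[Track, Track]] = {}
    citru: dict[str, tuple[Track, Track]] = {}
    for i, (chrom, length) in enumerate(genome.chromosomes):
        volk[chrom] = ([(float(length), RETICULATA)], [(float(length), MEDICA)])
        if citrumelo_breakpoints is None:
            breaks = [length / 2.0]
        else:
            breaks = sorted(citrumelo_breakpoints.get(chrom, []))
        for b in breaks:
            if not 0 < b < length:
                raise ValueError(f"breakpoint {b} outside chromosome {chrom}")
        first = RETICULATA if i % 2 == 0 else MAXIMA
        other = MAXIMA if first == RETICULATA else RETICULATA
        mosaic: Track = []
        lab = first
        for b in breaks:
            mosaic.append((float(b), lab))
            lab = other if lab == first else first
        mosaic.append((float(length), lab))
        citru[chrom] = ([(float(length), TRIFOLIATA)], _normalize(mosaic))
    return (ParentKaryotype("volkamer", volk),
            ParentKaryotype("citrumelo", citru))


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

@dataclass
class MeiosisParams:
    """Bivalent-only meiosis parameters.

    ``tau`` is the tetrasomic parameter 1 - PP, per chromosome (a scalar is
    broadcast).  Crossover counts per bivalent are Poisson with mean twice
    the chromosome's map length.  Double reduction is structurally
    impossible in this model and the flag only guards against misuse.
    """

    tau: dict[str, float] | float = 0.0
    double_reduction: bool = False

    def tau_of(self, chrom: str) -> float:
        t = self.tau[chrom] if isinstance(self.tau, dict) else float(self.tau)
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"tau for {chrom} outside [0, 1]: {t}")
        return t

    def __post_init__(self) -> None:
        if self.double_reduction:
            raise ValueError("double reduction is not modeled (bivalents only)")


@dataclass
class GameteTruth:
    """One diploid gamete: two transmitted chromatid ancestry tracks per
    chromosome plus the pairing configuration and crossover positions."""

    gamete_id: str
    chromatids: dict[str, tuple[Track, Track]]
    pairing: dict[str, str]
    crossovers: dict[str, list[float]]

    def ancestor_dose(self, chrom: str, positions: np.ndarray,
                      ancestor: str) -> np.ndarray:
        c1, c2 = self.chromatids[chrom]
        return (track_labels_at(c1, positions) == ancestor).astype(int) \
            + (track_labels_at(c2, positions) == ancestor).astype(int)


def _tail_swap(a: Track, b: Track, x: float) -> tuple[Track, Track]:
    """Exchange everything distal to position x between two chromatids."""

    def split(track: Track) -> tuple[Track, Track]:
        head: Track = []
        tail: Track = []
        prev = 0.0
        for end, lab in track:
            if end <= x:
                head.append((end, lab))
            else:
                if prev < x:
                    head.append((x, lab))
                tail.append((end, lab))
            prev = end
        return head, tail

    ha, ta = split(a)
    hb, tb = split(b)
    return ha + tb, hb + ta


def simulate_meiosis(parent: ParentKaryotype, genome: GenomeSpec,
                     params: MeiosisParams, n: int,
                     rng: np.random.Generator | None = None,
                     id_prefix: str = "g") -> list[GameteTruth]:
    """Simulate ``n`` diploid gametes of a doubled-diploid parent.

    Per chromosome the pairing configuration is homologous (identical
    copies pair) with probability 1 - 2 tau / 3 and each of the two
    heterologous configurations with probability tau / 3, which reproduces
    the centromeric gamete frequencies (tau/6, tau/6, 1 - tau/3).  Each
    bivalent receives a Poisson number of crossovers at uniform positions,
    every crossover tail-swapping one random chromatid of each partner (no
    chromatid interference); the gamete receives one random chromatid from
    each of the two bivalents.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    gametes = []
    for g in range(n):
        chromatids: dict[str, tuple[Track, Track]] = {}
        pairing: dict[str, str] = {}
        xovers: dict[str, list[float]] = {}
        for chrom, length in genome.chromosomes:
            tau = params.tau_of(chrom)
            h1, h2 = parent.haplotypes[chrom]
            u = rng.random()
            if u < 1.0 - 2.0 * tau / 3.0:
                config = HOMOLOGOUS
                bivalents = [(h1, h1), (h2, h2)]
            else:
                config = HETEROLOGOUS
                # the two heterologous configurations are exchangeable
                # because the homolog copies are identical
                bivalents = [(h1, h2), (h1, h2)]
            mean_xo = 2.0 * genome.map_lengths[chrom]
            transmitted: list[Track] = []
            positions: list[float] = []
            for p, q in bivalents:
                quad = [list(p), list(p), list(q), list(q)]
                n_xo = rng.poisson(mean_xo)
                for x in np.sort(rng.uniform(0.0, length, size=n_xo)):
                    i = rng.integers(2)
                    j = 2 + rng.integers(2)
                    quad[i], quad[j] = _tail_swap(quad[i], quad[j], float(x))
                    positions.append(float(x))
                transmitted.append(_normalize(quad[rng.integers(4)]))
            chromatids[chrom] = (transmitted[0], transmitted[1])
            pairing[chrom] = config
            xovers[chrom] = positions
        gametes.append(GameteTruth(f"{id_prefix}{g:04d}", chromatids,
                                   pairing, xovers))
    return gametes


def gamete_dose_matrix(gametes: list[GameteTruth],
                       sites: pd.DataFrame, ancestor: str,
                       site_ids: list[str] | None = None) -> pd.DataFrame:
    """True ancestor doses (0-2) of gametes at sites (chrom, pos) columns.

    Column order follows ``sites``; ``site_ids`` names the columns (defaults
    to ``chrom:pos``).
    """
    if site_ids is None:
        site_ids = [f"{c}:{int(p)}" for c, p in zip(sites["chrom"], sites["pos"])]
    data = np.zeros((len(gametes), len(sites)), dtype=int)
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        cols = sites.index.get_indexer(grp.index)
        for i, g in enumerate(gametes):
            data[i, cols] = g.ancestor_dose(chrom, pos, ancestor)
    return pd.DataFrame(data, index=[g.gamete_id for g in gametes],
                        columns=site_ids)


def truth_window_doses(gametes: list[GameteTruth],
                       panel_windows: pd.DataFrame,
                       ancestor: str) -> pd.DataFrame:
    """Ground-truth gamete dose per genomic window (majority dose over the
    window's member DSNP sites; ties go to the lower dose).

    ``panel_windows`` is a partitioned panel with a ``window_id`` column
    (see :func:`tetrameio.dosing.window_partition`).
    """
    sub = panel_windows[panel_windows["taxon"] == ancestor]
    wins = sub["window_id"].unique()
    out = np.zeros((len(gametes), len(wins)), dtype=float)
    col_of = {w: j for j, w in enumerate(wins)}
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        wids = grp["window_id"].to_numpy()
        for i, g in enumerate(gametes):
            d = g.ancestor_dose(chrom, pos, ancestor)
            for w in np.unique(wids):
                m = wids == w
                counts = np.bincount(d[m], minlength=3)
                out[i, col_of[w]] = int(np.argmax(counts))
    return pd.DataFrame(out, index=[g.gamete_id for g in gametes],
                        columns=list(wins))


# ---------------------------------------------------------------------------
# hybrids
# ---------------------------------------------------------------------------

@dataclass
class HybridTruth:
    """Tetraploid hybrid: the union of one ovule and one pollen gamete."""

    hybrid_id: str
    ovule: GameteTruth
    pollen: GameteTruth

    def ancestor_dose(self, chrom: str, positions: np.ndarray,
                      ancestor: str) -> np.ndarray:
        return self.ovule.ancestor_dose(chrom, positions, ancestor) \
            + self.pollen.ancestor_dose(chrom, positions, ancestor)


def form_hybrids(ovules: list[GameteTruth], pollens: list[GameteTruth],
                 rng: np.random.Generator | None = None,
                 n: int | None = None) -> list[HybridTruth]:
    """Unite ovules and pollens into tetraploid hybrids.

    With ``n`` unset the lists are paired positionally (must be equal
    length); otherwise ``n`` hybrids are formed by sampling one gamete from
    each list with replacement.
    """
    if not ovules or not pollens:
        raise ValueError("empty gamete list")
    if n is None:
        if len(ovules) != len(pollens):
            raise ValueError("unequal gamete lists; pass n to sample")
        pairs = list(zip(ovules, pollens))
    else:
        rng = np.random.default_rng() if rng is None else rng
        pairs = [(ovules[rng.integers(len(ovules))],
                  pollens[rng.integers(len(pollens))]) for _ in range(n)]
    return [HybridTruth(f"H{i:04d}", o, p) for i, (o, p) in enumerate(pairs)]


# ---------------------------------------------------------------------------
# diagnostic-SNP panel and reference accessions
# ---------------------------------------------------------------------------

def synthetic_dsnp_panel(genome: GenomeSpec, per_taxon_per_chrom: int = 240,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Plant taxon-diagnostic SNP positions along the genome.

    Each taxon receives ``per_taxon_per_chrom`` sites per chromosome where
    it is fixed for the alternate allele and the other taxa carry the
    reference allele.  Returns the truth panel (chrom, pos, taxon,
    diag_allele) sorted by position.
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for chrom, length in genome.chromosomes:
        total = per_taxon_per_chrom * len(ANCESTORS)
        pos = np.unique(rng.integers(1, length, size=3 * total))
        while len(pos) < total:  # vanishingly unlikely at realistic densities
            pos = np.unique(np.concatenate(
                [pos, rng.integers(1, length, size=total)]))
        pos = np.sort(rng.choice(pos, size=total, replace=False))
        taxa = np.repeat(ANCESTORS, per_taxon_per_chrom)
        rng.shuffle(taxa)
        for p, t in zip(pos, taxa):
            rows.append((chrom, int(p), t, "alt"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "taxon", "diag_allele"])
    return df.sort_values(["chrom", "pos"], ignore_index=True)


def synthetic_reference_genotypes(
    panel: pd.DataFrame, n_per_taxon: dict[str, int] | int = 2,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Diploid genotypes (alt-allele count 0/1/2, NaN missing) of reference
    accessions at the panel sites, plus the accession -> taxon map."""
    rng = np.random.default_rng() if rng is None else rng
    if isinstance(n_per_taxon, int):
        n_per_taxon = {t: n_per_taxon for t in ANCESTORS}
    accs, taxa = [], []
    for t in ANCESTORS:
        for i in range(n_per_taxon[t]):
            accs.append(f"{t[:3]}_{i}")
            taxa.append(t)
    geno = np.zeros((len(panel), len(accs)))
    for j, t in enumerate(taxa):
        geno[:, j] = np.where(panel["taxon"].to_numpy() == t, 2.0, 0.0)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = np.nan
    idx = pd.MultiIndex.from_frame(panel[["chrom", "pos"]])
    gdf = pd.DataFrame(geno, index=idx, columns=accs)
    return gdf, pd.Series(taxa, index=accs, name="taxon")


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

@dataclass
class ReadCountModel:
    """GBS-like coverage model over diagnostic SNPs: Poisson total depth,
    binomial diagnostic-allele reads with symmetric error ``eps``, and a
    per-site dropout (missing) rate."""

    depth: float = 20.0
    eps: float = 0.01
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0.0 <= self.eps < 0.5:
            raise ValueError("eps must be in [0, 0.5)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")


def simulate_read_counts(hybrids: list[HybridTruth], panel: pd.DataFrame,
                         model: ReadCountModel,
                         rng: np.random.Generator | None = None,
                         ploidy: int = 4) -> pd.DataFrame:
    """Per-site diagnostic-allele and total read counts for each hybrid.

    Total reads ~ Poisson(depth) (0 for dropout sites); diagnostic reads ~
    Binomial(total, f) with f = d / ploidy pushed off the boundaries by the
    error rate (f = eps at dose 0, 1 - eps at full dose).  Returns a long
    table (chrom, pos, taxon, sample, diag_reads, total_reads).
    """
    rng = np.random.default_rng() if rng is None else rng
    frames = []
    for chrom, grp in panel.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        for hyb in hybrids:
            dose = np.zeros(len(grp), dtype=int)
            for taxon in np.unique(grp["taxon"]):
                m = grp["taxon"].to_numpy() == taxon
                dose[m] = hyb.ancestor_dose(chrom, pos[m], taxon)
            total = rng.poisson(model.depth, size=len(grp))
            total[rng.random(len(grp)) < model.missing_rate] = 0
            f = np.clip(dose / ploidy, model.eps, 1.0 - model.eps)
            diag = rng.binomial(total, f)
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": grp["pos"].to_numpy(),
                "taxon": grp["taxon"].to_numpy(),
                "sample": hyb.hybrid_id,
                "diag_reads": diag, "total_reads": total,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(gamete_doses: pd.DataFrame,
                        effects: list[tuple[str, float]],
                        noise_sd: float = 1.0, intercept: float = 0.0,
                        rng: np.random.Generator | None = None,
                        trait: str = "trait") -> pd.DataFrame:
    """Additive QTL phenotypes: intercept + sum beta * dose + N(0, sd).

    ``gamete_doses`` is individuals x windows; each effect names a window
    column.  Missing doses contribute their column mean (mean imputation
    keeps the additive expectation unbiased).
    """
    y = np.full(len(gamete_doses), float(intercept))
    for window, beta in effects:
        if window not in gamete_doses.columns:
            raise KeyError(f"unknown window id {window!r}")
        col = gamete_doses[window].astype(float)
        col = col.fillna(col.mean())
        y = y + beta * col.to_numpy()
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    return pd.DataFrame({trait: y}, index=gamete_doses.index)
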