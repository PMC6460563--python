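"""Synthetic trio cohorts with known X-inactivation structure.

Real allele-specific-expression studies of X-inactivation need three things
that are hard to obtain together: trio genotypes on chrX (father hemizygous),
allele-resolved RNA-seq read counts in the daughters, and ground truth about
each individual's cell-population skew and each gene's inactivation status.
This module fabricates all three in a mutually consistent way so the entire
downstream pipeline (phasing, filtering, skew classification, escapee
testing, precursor-count fitting) can be validated against known truth.

The generative model
--------------------
* Each female's skew ``theta`` — the fraction of blood cells with the
  *paternal* X active — is ``Binomial(n_cells, 0.5) / n_cells``: every one of
  ``n_cells`` embryonic precursor cells independently inactivates the
  maternal or paternal X with probability 1/2, and the blood compartment
  descends clonally from that pool.
* At a heterozygous exonic SNV of an X-inactivated gene the expected
  paternal read fraction is ``theta``; an escapee gene is expressed from
  both alleles (fraction 0.5); *XIST* is expressed from the inactive X
  (fraction ``1 - theta``); variable escapees escape in a random subset of
  individuals. Pseudoautosomal (PAR) genes are diploid-expressed (0.5).
* Read counts are binomial draws at a negative-binomially distributed
  coverage, followed by binomial thinning of alternative-allele reads to
  emulate reference mapping bias (the slight leftward shift of allelic
  ratios away from 0.5 seen in real data).

Besides the informative sites (daughter-heterozygous, exonic, non-PAR,
coverage at least ``min_coverage``), every cohort contains decoy sites —
daughter-homozygous, PAR, non-exonic, and low-coverage — plus optional
Mendelian-inconsistent sites, so every downstream filter is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "Cohort",
    "GRCH37_PAR1",
    "GRCH37_PAR2",
    "draw_individual_skew",
    "simulate_skews",
    "generate_gene_annotation",
    "generate_trio_genotypes",
    "generate_counts",
    "generate_cohort",
]

# GRCh37 chrX pseudoautosomal regions, BED convention (0-based, half-open).
GRCH37_PAR1 = ("X", 60_000, 2_699_520)
GRCH37_PAR2 = ("X", 154_931_043, 155_260_560)

_BASES = np.array(list("ACGT"))

# Gene statuses understood by the count model.
GENE_STATUSES = ("inactivated", "escapee", "variable_escapee", "xist")


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort generator.

    Defaults describe a blood ASE study of healthy trios: an 8-precursor-cell
    skew model, 30-150 informative heterozygous SNVs per daughter, read
    coverage centred near 50x with a hard >=10 filter downstream, and a mild
    reference bias (``reference_bias=0.49``; 0.5 means no bias).
    """

    n_trios: int = 50
    n_cells: int = 8
    snvs_per_individual_range: tuple[int, int] = (30, 150)
    coverage_mean: float = 50.0
    coverage_dispersion: float = 8.0
    min_coverage: int = 10
    reference_bias: float = 0.49
    n_genes: int = 120
    escapee_fraction: float = 0.15
    variable_escapee_fraction: float = 0.3
    variable_escape_prob: float = 0.5
    mendelian_error_rate: float = 0.0
    hom_site_factor: float = 0.4
    n_par_sites: int = 5
    n_nonexonic_sites: int = 10
    n_lowcov_sites: int = 8
    chrom: str = "X"
    chrom_length: int = 155_270_560
    par_intervals: tuple[tuple[str, int, int], ...] = (GRCH37_PAR1, GRCH37_PAR2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        lo, hi = self.snvs_per_individual_range
        if not (1 <= lo <= hi):
            raise ValueError("snvs_per_individual_range must be a valid interval")
        if not (0.0 < self.reference_bias < 1.0):
            raise ValueError("reference_bias must be in (0, 1)")
        if not (0.0 <= self.escapee_fraction <= 1.0):
            raise ValueError("escapee_fraction must be in [0, 1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage model parameters must be positive")


@dataclass
class CohortTruth:
    """Ground truth exported alongside a cohort for validation.

    individuals: sample_id, trio_id, role (daughter/mother), theta
    genes: gene_id, status, region (nonpar/par)
    variable_escape: gene_id, sample_id, escapes — realized escape of
        variable escapees per individual
    sites: trio_id, chrom, pos, site_class, gene_id, paternal_allele
    """

    individuals: pd.DataFrame
    genes: pd.DataFrame
    variable_escape: pd.DataFrame
    sites: pd.DataFrame

    @property
    def xist_gene_id(self) -> str:
        hit = self.genes.loc[self.genes["status"] == "xist", "gene_id"]
        return str(hit.iloc[0])


@dataclass
class Cohort:
    """A complete self-consistent synthetic dataset."""

    config: CohortConfig
    trios: pd.DataFrame       # trio_id, daughter_id, mother_id, father_id
    genotypes: pd.DataFrame   # trio_id, chrom, pos, ref, alt, daughter_gt, mother_gt, father_allele
    counts: pd.DataFrame      # sample_id, chrom, pos, ref, alt, ref_count, alt_count
    exons: pd.DataFrame       # chrom, start, end, gene_id (BED, 0-based half-open)
    par: pd.DataFrame         # chrom, start, end (BED)
    truth: CohortTruth


def draw_individual_skew(n_cells: int, rng: np.random.Generator) -> float:
    """Draw one individual's true skew theta under the precursor-cell model.

    Each of ``n_cells`` precursor cells independently keeps the paternal X
    active with probability 1/2; theta is the fraction that did, so it is a
    multiple of ``1/n_cells`` with marginal law ``Binomial(n_cells, 0.5) /
    n_cells``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return float(rng.binomial(n_cells, 0.5)) / n_cells


def simulate_skews(n_cells: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized :func:`draw_individual_skew` (``size`` independent draws)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if size < 1:
        raise ValueError("size must be >= 1")
    return rng.binomial(n_cells, 0.5, size=size) / n_cells


# ---------------------------------------------------------------------------
# gene / exon annotation
# ---------------------------------------------------------------------------

_EXONS_PER_GENE = 5
_EXON_LEN = 1_000
_INTRON_LEN = 3_000
_GENE_REGION = (3_000_000, 154_500_000)   # non-PAR stretch used for gene placement
_PAR_DECOY_STARTS = (1_000_000, 1_100_000)


def generate_gene_annotation(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out genes along a synthetic X and assign inactivation statuses.

    Returns ``(exons, genes)``: a BED-style exon table and a gene truth table.
    ``n_genes`` genes are evenly tiled across the non-PAR chromosome body,
    each with five 1-kb exons. One mid-chromosome gene is designated *XIST*;
    of the rest, ``escapee_fraction`` are escapees and, among those,
    ``variable_escapee_fraction`` escape only in a subset of individuals.
    Two decoy genes sit inside PAR1 so that the PAR filter is exercised on
    exonic sites too.
    """
    start, end = _GENE_REGION
    slot = (end - start) / config.n_genes
    rows = []
    gene_rows = []
    xist_idx = config.n_genes // 2
    statuses = np.full(config.n_genes, "inactivated", dtype=object)
    is_escapee = rng.random(config.n_genes) < config.escapee_fraction
    is_variable = rng.random(config.n_genes) < config.variable_escapee_fraction
    statuses[is_escapee] = "escapee"
    statuses[is_escapee & is_variable] = "variable_escapee"
    statuses[xist_idx] = "xist"

    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gene_id = "XIST" if i == xist_idx else f"G{i + 1:0{width}d}"
        gstart = int(start + i * slot)
        for e in range(_EXONS_PER_GENE):
            estart = gstart + e * (_EXON_LEN + _INTRON_LEN)
            rows.append((config.chrom, estart, estart + _EXON_LEN, gene_id))
        gene_rows.append((gene_id, str(statuses[i]), "nonpar"))

    for j, gstart in enumerate(_PAR_DECOY_STARTS, start=1):
        gene_id = f"PARG{j:02d}"
        for e in range(_EXONS_PER_GENE):
            estart = gstart + e * (_EXON_LEN + _INTRON_LEN)
            rows.append((config.chrom, estart, estart + _EXON_LEN, gene_id))
        gene_rows.append((gene_id, "inactivated", "par"))

    exons = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "status", "region"])
    return exons, genes


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _sample_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def _gt(a: str, b: str) -> str:
    return "/".join(sorted((a, b)))


class _PositionPool:
    """Draws globally unique 1-based SNV positions from annotation regions."""

    def __init__(self, exons: pd.DataFrame, genes: pd.DataFrame,
                 config: CohortConfig, rng: np.random.Generator) -> None:
        self.rng = rng
        self.used: set[int] = set()
        nonpar_ids = set(genes.loc[genes["region"] == "nonpar", "gene_id"])
        np_mask = exons["gene_id"].isin(nonpar_ids).to_numpy()
        self.np_starts = exons["start"].to_numpy()[np_mask]
        self.np_ends = exons["end"].to_numpy()[np_mask]
        self.np_genes = exons["gene_id"].to_numpy()[np_mask]
        self.p_starts = exons["start"].to_numpy()[~np_mask]
        self.p_ends = exons["end"].to_numpy()[~np_mask]
        self.p_genes = exons["gene_id"].to_numpy()[~np_mask]
        order = np.argsort(exons["start"].to_numpy())
        self.all_starts = exons["start"].to_numpy()[order]
        self.all_ends = exons["end"].to_numpy()[order]
        self.par_intervals = config.par_intervals

    def _unique(self, draw) -> tuple[int, str | None]:
        while True:
            pos, gene = draw()
            if pos not in self.used:
                self.used.add(pos)
                return pos, gene

    def exonic_nonpar(self) -> tuple[int, str]:
        def draw():
            i = int(self.rng.integers(len(self.np_starts)))
            # 1-based position in (start, end]
            pos = int(self.rng.integers(self.np_starts[i] + 1, self.np_ends[i] + 1))
            return pos, str(self.np_genes[i])
        return self._unique(draw)  # type: ignore[return-value]

    def par(self) -> tuple[int, str | None]:
        def draw():
            if self.rng.random() < 0.5 and len(self.p_starts):
                i = int(self.rng.integers(len(self.p_starts)))
                return (int(self.rng.integers(self.p_starts[i] + 1, self.p_ends[i] + 1)),
                        str(self.p_genes[i]))
            chrom, s, e = self.par_intervals[int(self.rng.integers(len(self.par_intervals)))]
            return int(self.rng.integers(s + 1, e + 1)), None
        return self._unique(draw)

    def nonexonic(self) -> tuple[int, None]:
        lo, hi = _GENE_REGION
        def draw():
            while True:
                pos = int(self.rng.integers(lo + 1, hi + 1))
                i = np.searchsorted(self.all_starts, pos, side="right") - 1
                inside = i >= 0 and pos <= self.all_ends[i] and pos > self.all_starts[i]
                if not inside:
                    return pos, None
        return self._unique(draw)  # type: ignore[return-value]


def generate_trio_genotypes(
    config: CohortConfig,
    exons: pd.DataFrame,
    genes: pd.DataFrame,
    trios: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate Mendelian-consistent trio genotypes at private X SNVs.

    For every trio the daughter receives a target number of *informative*
    sites (heterozygous, exonic, non-PAR; count uniform in
    ``snvs_per_individual_range``) whose paternal allele equals the father's
    hemizygous allele and whose maternal allele is carried by the mother.
    Decoy sites — daughter-homozygous, PAR, non-exonic, designated
    low-coverage, and (if ``mendelian_error_rate > 0``) mother-inconsistent —
    are added on top so downstream filters and phasing checks all fire.

    Returns ``(genotypes, sites)`` where ``sites`` is the per-site truth
    table (site_class, generating gene, true paternal allele).
    """
    pool = _PositionPool(exons, genes, config, rng)
    lo, hi = config.snvs_per_individual_range
    geno_rows: list[tuple] = []
    site_rows: list[tuple] = []

    def add_site(trio_id: str, pos: int, gene_id: str | None, site_class: str,
                 het: bool = True, consistent: bool = True) -> None:
        ref, alt = _sample_alleles(rng)
        if het:
            paternal = ref if rng.random() < 0.5 else alt
            maternal = alt if paternal == ref else ref
            daughter_gt = _gt(ref, alt)
            if consistent:
                other = ref if rng.random() < 0.5 else alt
                mother_gt = _gt(maternal, other)
            else:
                # Mendelian error: mother carries only the paternal allele,
                # so the forced maternal allele is absent from her genotype.
                mother_gt = _gt(paternal, paternal)
        else:
            a = ref if rng.random() < 0.5 else alt
            paternal = maternal = a
            daughter_gt = _gt(a, a)
            other = ref if rng.random() < 0.5 else alt
            mother_gt = _gt(a, other)
        geno_rows.append((trio_id, config.chrom, pos, ref, alt,
                          daughter_gt, mother_gt, paternal))
        site_rows.append((trio_id, config.chrom, pos, site_class, gene_id, paternal))

    for trio_id in trios["trio_id"]:
        m_d = int(rng.integers(lo, hi + 1))
        for _ in range(m_d):
            pos, gene = pool.exonic_nonpar()
            add_site(trio_id, pos, gene, "informative")
        n_err = int(rng.binomial(m_d, config.mendelian_error_rate))
        for _ in range(n_err):
            pos, gene = pool.exonic_nonpar()
            add_site(trio_id, pos, gene, "mendelian_error", consistent=False)
        for _ in range(int(round(config.hom_site_factor * m_d))):
            pos, gene = pool.exonic_nonpar()
            add_site(trio_id, pos, gene, "homozygous", het=False)
        for _ in range(config.n_par_sites):
            pos, gene = pool.par()
            add_site(trio_id, pos, gene, "par")
        for _ in range(config.n_nonexonic_sites):
            pos, gene = pool.nonexonic()
            add_site(trio_id, pos, gene, "nonexonic")
        for _ in range(config.n_lowcov_sites):
            pos, gene = pool.exonic_nonpar()
            add_site(trio_id, pos, gene, "lowcov")

    genotypes = pd.DataFrame(
        geno_rows,
        columns=["trio_id", "chrom", "pos", "ref", "alt",
                 "daughter_gt", "mother_gt", "father_allele"],
    ).sort_values(["trio_id", "pos"], kind="stable").reset_index(drop=True)
    sites = pd.DataFrame(
        site_rows,
        columns=["trio_id", "chrom", "pos", "site_class", "gene_id", "paternal_allele"],
    ).sort_values(["trio_id", "pos"], kind="stable").reset_index(drop=True)
    return genotypes, sites


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _nb_coverage(n: int, config: CohortConfig, rng: np.random.Generator,
                 floor: int | None = None) -> np.ndarray:
    """Negative-binomial coverage draws, optionally floored at ``floor``."""
    r = config.coverage_dispersion
    p = r / (r + config.coverage_mean)
    cov = rng.negative_binomial(r, p, size=n)
    if floor is not None:
        cov = np.maximum(cov, floor)
    return cov


def _thin_reference_bias(ref: np.ndarray, alt: np.ndarray, beta: float,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Binomially thin reads of the disfavoured allele.

    ``beta`` is the relative capture probability of alternative-allele reads;
    at 0.5 nothing happens, below 0.5 each alt read survives with probability
    ``beta / (1 - beta)``, above 0.5 the roles are swapped.
    """
    if beta == 0.5:
        return ref, alt
    if beta < 0.5:
        keep = beta / (1.0 - beta)
        return ref, rng.binomial(alt, keep)
    keep = (1.0 - beta) / beta
    return rng.binomial(ref, keep), alt


def _expected_paternal_fraction(status: np.ndarray, escapes: np.ndarray,
                                theta: np.ndarray) -> np.ndarray:
    """Per-site expected paternal read fraction given gene status and skew."""
    f = theta.astype(float).copy()
    f[status == "escapee"] = 0.5
    f[status == "par"] = 0.5
    var = status == "variable_escapee"
    f[var & escapes] = 0.5
    xist = status == "xist"
    f[xist] = 1.0 - theta[xist]
    unknown = ~np.isin(status, ("inactivated", "escapee", "variable_escapee",
                                "xist", "par", "intergenic"))
    if unknown.any():
        bad = sorted(set(status[unknown]))
        raise ValueError(f"unknown gene status: {bad}")
    return f


def generate_counts(
    genotypes: pd.DataFrame,
    sites: pd.DataFrame,
    truth: CohortTruth,
    trios: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate allele-specific read counts for daughters and mothers.

    Daughters: at every site, coverage is drawn from the negative-binomial
    model (designated low-coverage decoys get < ``min_coverage`` reads);
    paternal reads are ``Binomial(coverage, f)`` with ``f`` set by the
    generating gene's status and the daughter's skew; reads are then
    relabelled ref/alt and alternative reads thinned by the reference bias.
    Sites designated informative are redrawn until they still pass the
    coverage filter after thinning, preserving the per-individual
    informative-SNV guarantee.

    Mothers: counts are produced at their heterozygous sites by the same
    scheme using their own (independent) skew; which allele lies on the
    majority-active X is drawn per site, which is immaterial downstream
    because mothers are analysed only through the orientation-free measure
    of balance.
    """
    theta_by_sample = truth.individuals.set_index("sample_id")["theta"]
    status_by_gene = truth.genes.set_index("gene_id")["status"]
    par_genes = set(truth.genes.loc[truth.genes["region"] == "par", "gene_id"])
    vesc = {(r.gene_id, r.sample_id): bool(r.escapes)
            for r in truth.variable_escape.itertuples()}
    trio_map = trios.set_index("trio_id")

    df = genotypes.merge(sites, on=["trio_id", "chrom", "pos"], how="left",
                         validate="one_to_one")
    # one unified per-site gene status label for the count model
    def site_status(row_gene, row_class):
        if row_class == "par" or row_gene in par_genes:
            return "par"
        if row_gene is None or (isinstance(row_gene, float) and np.isnan(row_gene)):
            return "intergenic"
        return str(status_by_gene[row_gene])

    df["model_status"] = [site_status(g, c) for g, c in
                          zip(df["gene_id"], df["site_class"])]

    out_frames = []
    for role in ("daughter", "mother"):
        sub = df.copy()
        sub["sample_id"] = trio_map.loc[sub["trio_id"], f"{role}_id"].to_numpy()
        if role == "mother":
            a = sub["mother_gt"].str.split("/", expand=True)
            het = a[0] != a[1]
            sub = sub[het].reset_index(drop=True)
            allele_a, allele_b = a[0][het].to_numpy(), a[1][het].to_numpy()
            # per-site coin: which of the mother's alleles rides the
            # majority-active haplotype
            flip = rng.random(len(sub)) < 0.5
            active_allele = np.where(flip, allele_a, allele_b)
        else:
            sub = sub.reset_index(drop=True)
            active_allele = sub["paternal_allele"].to_numpy()

        n = len(sub)
        theta = theta_by_sample.loc[sub["sample_id"]].to_numpy(dtype=float)
        status = sub["model_status"].to_numpy(dtype=object)
        escapes = np.array([vesc.get((g, s), False) for g, s in
                            zip(sub["gene_id"], sub["sample_id"])])
        f = _expected_paternal_fraction(status, escapes, theta)

        dgt = sub["daughter_gt"].str.split("/", expand=True)
        if role == "daughter":
            is_hom = (dgt[0] == dgt[1]).to_numpy()
        else:
            is_hom = np.zeros(n, dtype=bool)

        lowcov = (sub["site_class"] == "lowcov").to_numpy() if role == "daughter" \
            else np.zeros(n, dtype=bool)
        informative = (sub["site_class"] == "informative").to_numpy() if role == "daughter" \
            else np.zeros(n, dtype=bool)

        ref_allele = sub["ref"].to_numpy()
        beta = config.reference_bias

        def draw(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            m = int(mask.sum())
            cov = np.where(lowcov[mask], rng.integers(0, config.min_coverage, size=m),
                           _nb_coverage(m, config, rng, floor=config.min_coverage))
            active = rng.binomial(cov, f[mask])
            inactive = cov - active
            # homozygous daughters: every read carries the single allele
            hom_here = is_hom[mask]
            active = np.where(hom_here, cov, active)
            inactive = np.where(hom_here, 0, inactive)
            act_is_ref = active_allele[mask] == ref_allele[mask]
            refs = np.where(act_is_ref, active, inactive)
            alts = np.where(act_is_ref, inactive, active)
            return _thin_reference_bias(refs, alts, beta, rng)

        mask = np.ones(n, dtype=bool)
        ref_counts = np.zeros(n, dtype=int)
        alt_counts = np.zeros(n, dtype=int)
        # redraw informative sites whose post-thinning total slipped under
        # the coverage filter, so the informative-count guarantee holds
        while mask.any():
            r, a = draw(mask)
            idx = np.flatnonzero(mask)
            ref_counts[idx] = r
            alt_counts[idx] = a
            short = informative & (ref_counts + alt_counts < config.min_coverage)
            mask = mask & short

        out = pd.DataFrame({
            "sample_id": sub["sample_id"],
            "chrom": sub["chrom"],
            "pos": sub["pos"],
            "ref": sub["ref"],
            "alt": sub["alt"],
            "ref_count": ref_counts,
            "alt_count": alt_counts,
        })
        out_frames.append(out)

    counts = pd.concat(out_frames, ignore_index=True)
    return counts.sort_values(["sample_id", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig | None = None, **overrides) -> Cohort:
    """Generate a complete cohort bundle from a single master seed.

    Keyword overrides are applied on top of ``config`` (or the defaults), so
    ``generate_cohort(n_trios=10, seed=3)`` is a convenient spelling. Each
    stage (annotation, skews, genotypes, counts) draws from its own named
    substream of the master seed; a fixed seed yields a bit-identical bundle.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)

    exons, genes = generate_gene_annotation(config, substream(config.seed, "genes"))

    width = len(str(config.n_trios))
    trio_ids = [f"T{i + 1:0{width}d}" for i in range(config.n_trios)]
    trios = pd.DataFrame({
        "trio_id": trio_ids,
        "daughter_id": [t + "-D" for t in trio_ids],
        "mother_id": [t + "-M" for t in trio_ids],
        "father_id": [t + "-F" for t in trio_ids],
    })

    rng_skew = substream(config.seed, "skew")
    individuals = []
    for t in trio_ids:
        for role, col in (("daughter", "daughter_id"), ("mother", "mother_id")):
            sid = trios.loc[trios["trio_id"] == t, col].iloc[0]
            individuals.append((sid, t, role, draw_individual_skew(config.n_cells, rng_skew)))
    individuals = pd.DataFrame(individuals, columns=["sample_id", "trio_id", "role", "theta"])

    rng_var = substream(config.seed, "variable_escape")
    var_genes = genes.loc[genes["status"] == "variable_escapee", "gene_id"]
    ve_rows = [(g, s, bool(rng_var.random() < config.variable_escape_prob))
               for g in var_genes for s in individuals["sample_id"]]
    variable_escape = pd.DataFrame(ve_rows, columns=["gene_id", "sample_id", "escapes"])

    truth = CohortTruth(individuals=individuals, genes=genes,
                        variable_escape=variable_escape,
                        sites=pd.DataFrame())  # filled below

    genotypes, sites = generate_trio_genotypes(
        config, exons, genes, trios, substream(config.seed, "genotypes"))
    truth.sites = sites

    counts = generate_counts(genotypes, sites, truth, trios, config,
                             substream(config.seed, "counts"))

    par = pd.DataFrame(list(config.par_intervals), columns=["chrom", "start", "end"])
    return Cohort(config=config, trios=trios, genotypes=genotypes, counts=counts,
                  exons=exons, par=par, truth=truth)
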