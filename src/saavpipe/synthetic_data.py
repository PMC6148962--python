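"""Seeded generators for every pipeline input, with known ground truth.

The generators emulate the study design the pipeline targets: a tumour
cohort of 21 non-metastatic (NM) and 23 metastatic (MT) primaries with
paired adjacent-normal (PN) tissue; protein-level substitutions planted as
NM-only, MT-only or shared; shotgun peptide detection with dropout; a
copy-number -> mRNA -> protein cascade whose noise is calibrated by
bisection so the mean per-gene Spearman correlations hit configured
targets (defaults 0.53 for mRNA-protein and 0.41 for CNV-protein, the
magnitudes typical of tumour multi-omics cohorts); and exponential
survival with group-dependent hazard plus censoring.

Everything is deterministic given the seed.  Packaged fixtures transcribe
published SAAV tables verbatim (NM-specific, shared, and MT-specific
variant peptide lists) for desk-scale checks; known inconsistencies in
the printed source are annotated in each fixture's ``note`` column, and
the MT-specific table's in-text protein count (5) disagrees with its 7
printed rows — the fixture reproduces the rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import (CANONICAL_AA, CHROMOSOMES, GeneAnnotation, ProteinSeq,
                      QuantMatrix, SaavEvent, SurvivalRecord)
from .digestion import digest
from .errors import ValidationError


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    # proteome
    n_proteins: int = 120
    protein_len_min: int = 150
    protein_len_max: int = 600
    mean_peptide_len: float = 14.0   # tunes K/R frequency (1/mean)
    # cohorts (sample counts)
    n_pn: int = 44
    n_nm: int = 21
    n_mt: int = 23
    # planted substitutions per class
    n_nm_specific: int = 12
    n_mt_specific: int = 11
    n_shared: int = 26
    max_carriers: int = 3            # samples carrying each event, per cohort
    # peptide detection
    detection_prob: float = 0.8
    log_intensity_mean: float = 23.0
    log_intensity_sd: float = 2.0
    # quant cascade
    n_genes: int = 150
    n_cascade_samples: int = 30
    target_rho_mrna_protein: float = 0.53
    target_rho_cnv_protein: float = 0.41
    de_fraction: float = 0.1
    de_effect: float = 1.5           # log2-scale shift for planted DE genes
    # survival
    baseline_hazard: float = 0.02    # events per month
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.3

    def __post_init__(self):
        for name in ("detection_prob", "de_fraction", "censoring_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        for name in ("n_proteins", "n_pn", "n_nm", "n_mt", "n_genes",
                     "n_cascade_samples"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def nm_samples(self) -> list[str]:
        return [f"NM{i:02d}" for i in range(1, self.n_nm + 1)]

    def mt_samples(self) -> list[str]:
        return [f"MT{i:02d}" for i in range(1, self.n_mt + 1)]

    def pn_samples(self) -> list[str]:
        return [f"PN{i:02d}" for i in range(1, self.n_pn + 1)]


# ---------------------------------------------------------------------------
# Proteome + planted substitutions
# ---------------------------------------------------------------------------

def generate_proteome(cfg: SimulationConfig,
                      rng: np.random.Generator | None = None) -> list[ProteinSeq]:
    """Random proteome with K/R frequency set to 1/mean_peptide_len.

    A tryptic fragment ends at each K/R, so the fragment length is
    geometric with mean 1/p; targeting ~14 residues gives realistic
    digests.  Deterministic for a given config seed.
    """
    rng = rng or cfg.rng()
    p_kr = 1.0 / cfg.mean_peptide_len
    others = [aa for aa in CANONICAL_AA if aa not in "KR"]
    probs = np.array([p_kr / 2 if aa in "KR" else (1 - p_kr) / len(others)
                      for aa in CANONICAL_AA])
    letters = np.array(list(CANONICAL_AA))
    proteins = []
    for i in range(cfg.n_proteins):
        length = int(rng.integers(cfg.protein_len_min,
                                  cfg.protein_len_max + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        proteins.append(ProteinSeq(accession=f"SYN{i:05d}", sequence=seq))
    return proteins


def plant_saavs(proteome: list[ProteinSeq], cfg: SimulationConfig,
                rng: np.random.Generator | None = None):
    """Plant substitutions with a known cohort design.

    Returns ``(events, truth)``: sample-level :class:`SaavEvent` rows (one
    per carrier sample) and a truth ledger DataFrame recording each
    event's intended class and carriers.  Reference residues are read from
    the sequence, so every event passes the reference check by
    construction.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    nm, mt = cfg.nm_samples(), cfg.mt_samples()
    design = ([("NM-specific", [nm])] * cfg.n_nm_specific
              + [("MT-specific", [mt])] * cfg.n_mt_specific
              + [("shared", [nm, mt])] * cfg.n_shared)
    used: set[tuple[str, int]] = set()
    events, truth_rows = [], []
    for true_class, pools in design:
        while True:
            prot = proteome[int(rng.integers(len(proteome)))]
            pos = int(rng.integers(1, len(prot) + 1))
            if (prot.accession, pos) not in used:
                used.add((prot.accession, pos))
                break
        ref = prot.sequence[pos - 1]
        alt = str(rng.choice([aa for aa in CANONICAL_AA if aa != ref]))
        carriers = []
        for pool in pools:
            k = int(rng.integers(1, min(cfg.max_carriers, len(pool)) + 1))
            chosen = rng.choice(pool, size=k, replace=False)
            carriers.extend(str(s) for s in chosen)
        for sample in carriers:
            events.append(SaavEvent(
                accession=prot.accession, position=pos, ref=ref, alt=alt,
                sample=sample, cohort=sample[:2]))
        truth_rows.append({
            "accession": prot.accession, "position": pos, "ref": ref,
            "alt": alt, "site": f"{ref}{pos}{alt}",
            "true_class": true_class, "n_carriers": len(carriers),
            "carriers": ",".join(sorted(carriers))})
    truth = pd.DataFrame(truth_rows, columns=[
        "accession", "position", "ref", "alt", "site", "true_class",
        "n_carriers", "carriers"])
    return events, truth


# ---------------------------------------------------------------------------
# Peptide identifications
# ---------------------------------------------------------------------------

def simulate_peptide_ids(proteome: list[ProteinSeq], index: pd.DataFrame,
                         truth: pd.DataFrame, cfg: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         samples: list[str] | None = None) -> pd.DataFrame:
    """Per-sample peptide observations with dropout.

    Every wild-type tryptic peptide is observed with ``detection_prob`` in
    every sample; each mutant database peptide only in the samples
    carrying its event, with the same probability.  Intensities are
    log-normal.  Returns a peptide-id table (sample, cohort, peptide,
    intensity).
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    if samples is None:
        samples = cfg.nm_samples() + cfg.mt_samples()
    wild = sorted({p.sequence for prot in proteome for p in digest(prot)})
    carriers_of = {}
    site_rows = index.merge(
        truth[["accession", "site", "carriers"]],
        on=["accession", "site"], how="left")
    for row in site_rows.itertuples():
        carr = row.carriers if isinstance(row.carriers, str) else ""
        carriers_of.setdefault(row.mutant_peptide, set()).update(
            s for s in carr.split(",") if s)
    rows = []
    wild_arr = np.array(wild)
    for sample in samples:
        detected = wild_arr[rng.random(len(wild_arr)) < cfg.detection_prob]
        mutants = [m for m, carr in carriers_of.items() if sample in carr
                   and rng.random() < cfg.detection_prob]
        peptides = list(detected) + mutants
        intens = np.exp2(rng.normal(cfg.log_intensity_mean,
                                    cfg.log_intensity_sd, len(peptides)))
        cohort = sample[:2]
        rows.extend({"sample": sample, "cohort": cohort, "peptide": pep,
                     "intensity": float(x)}
                    for pep, x in zip(peptides, intens))
    return pd.DataFrame(rows, columns=["sample", "cohort", "peptide",
                                       "intensity"])


# ---------------------------------------------------------------------------
# CNV -> mRNA -> protein cascade
# ---------------------------------------------------------------------------

def _mean_rowwise_spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra = rankdata(a, axis=1)
    rb = rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra ** 2).sum(axis=1) * (rb ** 2).sum(axis=1))
    return float(np.mean(num / den))


def _bisect_noise(objective, lo=1e-6, hi=64.0, tol=1e-4, n_iter=60):
    """Find sigma with objective(sigma)=0; objective decreasing in sigma."""
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo < 0:       # even minimal noise overshoots downward
        return lo
    if f_hi > 0:       # even huge noise cannot reach the target
        return hi
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if objective(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


@dataclass
class SimulatedCascade:
    """Outputs plus ground truth of the quantification cascade."""

    segments: pd.DataFrame
    mrna: QuantMatrix
    protein: QuantMatrix
    cnv: pd.DataFrame                 # gene x sample latent copy number
    annotation: list[GeneAnnotation]
    groups: dict                      # sample -> "A"/"B"
    de_genes: set
    achieved_rho_mrna_protein: float
    achieved_rho_cnv_protein: float
    sigma_mrna: float
    sigma_protein: float


def default_annotation(genes: list[str],
                       gene_span: int = 100_000,
                       spacing: int = 1_000_000) -> list[GeneAnnotation]:
    """Lay genes out round-robin across chromosomes 1..22, X."""
    chroms = list(CHROMOSOMES[:23])
    per_chrom: dict[str, int] = {}
    out = []
    for i, gene in enumerate(genes):
        chrom = chroms[i % len(chroms)]
        k = per_chrom.get(chrom, 0)
        per_chrom[chrom] = k + 1
        start = 1 + k * spacing
        out.append(GeneAnnotation(gene=gene, chromosome=chrom, start=start,
                                  end=start + gene_span - 1))
    return out


def simulate_quant_cascade(cfg: SimulationConfig,
                           annotation: list[GeneAnnotation] | None = None,
                           rng: np.random.Generator | None = None
                           ) -> SimulatedCascade:
    """Generate CNV segments plus mRNA and protein matrices.

    The latent gene copy number (log-ratio scale) drives mRNA through an
    additive Gaussian noise channel, and mRNA drives protein likewise.
    The two noise scales are calibrated by nested bisection on the
    realized data so that the mean per-gene Spearman correlations hit the
    configured targets: the inner search sets the protein noise for the
    mRNA-protein target, the outer search sets the mRNA noise for the
    CNV-protein target.  A ``de_fraction`` of genes receives a copy-number
    shift in group B samples, which propagates down the cascade and
    defines the planted triple-concordant truth.
    """
    for t in (cfg.target_rho_mrna_protein, cfg.target_rho_cnv_protein):
        if t > 0.99:
            raise ValidationError(f"correlation target {t} unreachable")
    rng = rng or np.random.default_rng(cfg.seed + 3)
    g, n = cfg.n_genes, cfg.n_cascade_samples
    genes = [f"G{i:04d}" for i in range(1, g + 1)]
    samples = [f"S{i:02d}" for i in range(1, n + 1)]
    groups = {s: ("A" if i < n // 2 else "B") for i, s in enumerate(samples)}

    z = rng.standard_normal((g, n))
    n_de = int(round(cfg.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False) if n_de else np.array([], int)
    b_cols = np.array([groups[s] == "B" for s in samples])
    signs = rng.choice([-1.0, 1.0], size=n_de)
    for j, idx in enumerate(de_idx):
        z[idx, b_cols] += signs[j] * cfg.de_effect
    eps_m = rng.standard_normal((g, n))
    eps_p = rng.standard_normal((g, n))

    def calibrated_protein(mrna_vals):
        if cfg.target_rho_mrna_protein <= 0:
            # swamp the signal: noise many orders above the layer's scale
            sig = 1e6 * max(1.0, float(np.std(mrna_vals)))
            return mrna_vals + sig * eps_p, sig
        sig_p = _bisect_noise(
            lambda s: _mean_rowwise_spearman(mrna_vals, mrna_vals + s * eps_p)
            - cfg.target_rho_mrna_protein)
        return mrna_vals + sig_p * eps_p, sig_p

    def outer(sig_m):
        mrna_vals = z + sig_m * eps_m
        prot_vals, _ = calibrated_protein(mrna_vals)
        return _mean_rowwise_spearman(z, prot_vals) - cfg.target_rho_cnv_protein

    if cfg.target_rho_cnv_protein <= 0:
        sigma_m = 1e6
    else:
        sigma_m = _bisect_noise(outer)
    mrna_vals = z + sigma_m * eps_m
    prot_vals, sigma_p = calibrated_protein(mrna_vals)

    cnv = pd.DataFrame(z, index=genes, columns=samples)
    mrna = QuantMatrix(pd.DataFrame(mrna_vals, index=genes, columns=samples),
                       scale="log2")
    protein = QuantMatrix(pd.DataFrame(prot_vals, index=genes,
                                       columns=samples), scale="log2")
    if annotation is None:
        annotation = default_annotation(genes)
    span_of = {a.gene: a for a in annotation}
    seg_rows = []
    for gene in genes:
        ann = span_of[gene]
        for s in samples:
            seg_rows.append({"sample": s, "chromosome": ann.chromosome,
                             "start": ann.start, "end": ann.end,
                             "value": float(cnv.at[gene, s])})
    segments = pd.DataFrame(seg_rows, columns=["sample", "chromosome",
                                               "start", "end", "value"])
    return SimulatedCascade(
        segments=segments, mrna=mrna, protein=protein, cnv=cnv,
        annotation=annotation, groups=groups,
        de_genes={genes[i] for i in de_idx},
        achieved_rho_mrna_protein=_mean_rowwise_spearman(mrna_vals, prot_vals),
        achieved_rho_cnv_protein=_mean_rowwise_spearman(z, prot_vals),
        sigma_mrna=sigma_m, sigma_protein=sigma_p)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def simulate_survival(cfg: SimulationConfig, groups: dict,
                      rng: np.random.Generator | None = None
                      ) -> list[SurvivalRecord]:
    """Exponential event times with group-dependent hazard and censoring.

    ``groups`` maps sample id to stratum; the "high" stratum's hazard is
    ``baseline_hazard * hazard_ratio``, every other stratum runs at
    baseline.  With probability ``censoring_rate`` a subject is censored
    at a uniform fraction of its (unobserved) event time.
    """
    if cfg.hazard_ratio <= 0:
        raise ValidationError("hazard_ratio must be positive")
    rng = rng or np.random.default_rng(cfg.seed + 4)
    records = []
    for sample, group in groups.items():
        lam = cfg.baseline_hazard * (cfg.hazard_ratio if group == "high"
                                     else 1.0)
        t = float(rng.exponential(1.0 / lam))
        if rng.random() < cfg.censoring_rate:
            records.append(SurvivalRecord(sample=sample,
                                          time=t * float(rng.random()),
                                          event=0, group=group))
        else:
            records.append(SurvivalRecord(sample=sample, time=t, event=1,
                                          group=group))
    return records


# ---------------------------------------------------------------------------
# Packaged fixtures (published SAAV tables)
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table2", "table3", "table4")
_FIXTURE_COHORTS = {"table2": ("NM",), "table3": ("NM", "MT"),
                    "table4": ("MT",)}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged SAAV table fixture by name.

    Columns: protein, accession, wild_peptide, mutant_peptide, span, site,
    count, note.  ``count`` follows occurrence semantics (patients carrying
    the variant), and ``note`` flags rows whose printed site letter
    disagrees with the peptide pair.
    """
    if name not in FIXTURE_NAMES:
        raise ValidationError(f"unknown fixture {name!r}; "
                              f"choose from {FIXTURE_NAMES}")
    ref = resources.files("saavpipe") / "fixtures" / f"{name}.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["count"] = df["count"].astype(int)
    return df


def fixture_observations(name: str) -> pd.DataFrame:
    """Expand a table fixture into per-sample SAAV observations.

    Each row contributes ``count`` observations drawn from the table's
    cohort(s): NM samples for the NM-specific table, MT samples for the
    MT-specific table, and alternating NM/MT (starting with NM) for the
    shared table so that every shared event is seen in both cohorts.
    Deterministic sample ids make the expansion reproducible.
    """
    df = load_fixture(name)
    cohorts = _FIXTURE_COHORTS[name]
    rows = []
    for rec in df.itertuples():
        for j in range(rec.count):
            cohort = cohorts[j % len(cohorts)]
            idx = j // len(cohorts) + 1
            rows.append({
                "sample": f"{cohort}{idx:02d}", "cohort": cohort,
                "accession": rec.accession, "site": rec.site,
                "span_id": rec.span, "peptide": rec.mutant_peptide,
                "intensity": 1.0, "n_peptides": 1})
    return pd.DataFrame(rows, columns=["sample", "cohort", "accession",
                                       "site", "span_id", "peptide",
                                       "intensity", "n_peptides"])
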