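"""CNV -> mRNA -> protein integration.

Copy-number segments are summarized to gene level by the length-weighted
mean of overlapping segment values (or the single maximally-overlapping
segment).  Per-gene Spearman correlations are then computed across shared
samples for each layer pair, and the concordant gene sets intersected:
genes differential at both mRNA and protein level with consistent
direction, further intersected with copy-number-changed genes, tallied per
chromosome to expose hotspot regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CHROMOSOMES, GeneAnnotation, QuantMatrix
from .errors import ValidationError
from .quant import bh_adjust


def spearman(x, y) -> float:
    """Spearman rank correlation with pairwise-complete missing handling.

    Ties receive mid-ranks (the result is the Pearson correlation of the
    rank vectors).  Fewer than 3 complete pairs, or a constant vector,
    yield NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        warnings.warn("fewer than 3 complete pairs; rho undefined",
                      UserWarning, stacklevel=2)
        return float("nan")
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        warnings.warn("constant vector; rho undefined", UserWarning,
                      stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(xs, ys).statistic)


def gene_level_cnv(segments: pd.DataFrame, annotation: list[GeneAnnotation],
                   samples=None, method: str = "length_weighted") -> pd.DataFrame:
    """Summarize copy-number segments to a gene x sample matrix.

    ``method`` is ``length_weighted`` (mean of overlapping segment values
    weighted by overlap length) or ``max_overlap`` (value of the single
    largest-overlap segment).  Genes with no overlapping segment in a
    sample get NaN (flagged absent).
    """
    if method not in ("length_weighted", "max_overlap"):
        raise ValidationError(f"unknown method {method!r}")
    bad_seg = sorted(set(segments["chromosome"]) - set(CHROMOSOMES))
    bad_ann = sorted({a.chromosome for a in annotation} - set(CHROMOSOMES))
    if bad_seg or bad_ann:
        raise ValidationError(
            f"chromosome naming mismatch; offending labels: "
            f"segments={bad_seg} annotation={bad_ann}")
    sample_ids = list(samples) if samples is not None \
        else sorted(segments["sample"].unique())
    by_chrom = {chrom: sub for chrom, sub in segments.groupby("chromosome")}
    out = pd.DataFrame(np.nan, index=[a.gene for a in annotation],
                       columns=sample_ids)
    for ann in annotation:
        sub = by_chrom.get(ann.chromosome)
        if sub is None:
            continue
        ov = (np.minimum(sub["end"].to_numpy(), ann.end)
              - np.maximum(sub["start"].to_numpy(), ann.start) + 1)
        hit = ov > 0
        if not hit.any():
            continue
        hits = sub.loc[hit].assign(_ov=ov[hit])
        for sample, rows in hits.groupby("sample"):
            if sample not in out.columns:
                continue
            if method == "length_weighted":
                val = np.average(rows["value"], weights=rows["_ov"])
            else:
                val = rows.loc[rows["_ov"].idxmax(), "value"]
            out.at[ann.gene, sample] = val
    return out


def _pairwise_rho(a: pd.DataFrame, b: pd.DataFrame, min_samples: int):
    """Per-row Spearman between two aligned gene x sample frames."""
    rhos, pvals, ns = [], [], []
    for gene in a.index:
        x = a.loc[gene].to_numpy(dtype=float)
        y = b.loc[gene].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        ns.append(n)
        if n < max(3, min_samples) or np.all(x[ok] == x[ok][0]) \
                or np.all(y[ok] == y[ok][0]):
            rhos.append(np.nan)
            pvals.append(np.nan)
            continue
        res = stats.spearmanr(x[ok], y[ok])
        rhos.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    return np.array(rhos), np.array(pvals), np.array(ns)


@dataclass
class IntegrationResult:
    """Per-gene layer correlations plus layer-mean summaries."""

    per_gene: pd.DataFrame
    mean_rho_mrna_protein: float
    mean_rho_cnv_protein: float
    mean_rho_cnv_mrna: float


def correlate_layers(cnv: pd.DataFrame, mrna: QuantMatrix,
                     protein: QuantMatrix, min_samples: int = 5,
                     adjust: str = "fdr_bh") -> IntegrationResult:
    """Per-gene Spearman correlation for each layer pair.

    Correlations run across the samples shared by each pair of layers;
    layer means average per-gene rhos over genes with at least
    ``min_samples`` complete pairs.  Per-gene p-values are BH-adjusted
    (``adjust=None`` skips).
    """
    genes = [g for g in cnv.index
             if g in mrna.data.index and g in protein.data.index]
    if not genes:
        raise ValidationError("no genes shared across the three layers")

    def shared(x: pd.DataFrame, y: pd.DataFrame):
        cols = [c for c in x.columns if c in y.columns]
        if len(cols) < 3:
            raise ValidationError("fewer than 3 shared samples for a "
                                  "layer pair")
        return x.loc[genes, cols], y.loc[genes, cols]

    m_p = _pairwise_rho(*shared(mrna.data, protein.data), min_samples)
    c_p = _pairwise_rho(*shared(cnv, protein.data), min_samples)
    c_m = _pairwise_rho(*shared(cnv, mrna.data), min_samples)

    per_gene = pd.DataFrame({
        "gene": genes,
        "rho_mrna_protein": m_p[0], "p_mrna_protein": m_p[1],
        "rho_cnv_protein": c_p[0], "p_cnv_protein": c_p[1],
        "rho_cnv_mrna": c_m[0], "p_cnv_mrna": c_m[1],
        "n_mrna_protein": m_p[2], "n_cnv_protein": c_p[2],
        "n_cnv_mrna": c_m[2]})
    if adjust == "fdr_bh":
        for tag in ("mrna_protein", "cnv_protein", "cnv_mrna"):
            p = per_gene[f"p_{tag}"].to_numpy()
            ok = ~np.isnan(p)
            q = np.full_like(p, np.nan)
            if ok.any():
                q[ok] = bh_adjust(p[ok])
            per_gene[f"q_{tag}"] = q
    return IntegrationResult(
        per_gene=per_gene,
        mean_rho_mrna_protein=float(np.nanmean(m_p[0])),
        mean_rho_cnv_protein=float(np.nanmean(c_p[0])),
        mean_rho_cnv_mrna=float(np.nanmean(c_m[0])))


@dataclass
class ConcordantSets:
    """Nested concordant gene sets with chromosome hotspot tallies."""

    mrna_protein: set
    triple: set
    tally: pd.DataFrame   # chromosome, n_genes; ranked descending


def concordant_sets(de_protein: pd.DataFrame, de_mrna: pd.DataFrame,
                    cnv_changed: set, annotation: list[GeneAnnotation],
                    direction_consistent: bool = True) -> ConcordantSets:
    """Intersect differential calls across layers and tally chromosomes.

    ``de_protein``/``de_mrna`` are DE result frames (feature, direction)
    where direction is up/down/ns.  With ``direction_consistent`` a gene
    must move the same way at both layers.  The triple set additionally
    requires membership in ``cnv_changed``.  Tallies rank chromosomes by
    triple-set gene count, descending, ties broken by chromosome order
    1..22, X, Y.
    """
    def calls(df: pd.DataFrame) -> dict:
        return {row.feature: row.direction for row in df.itertuples()
                if row.direction in ("up", "down")}

    prot, rna = calls(de_protein), calls(de_mrna)
    if direction_consistent:
        both = {g for g in prot.keys() & rna.keys() if prot[g] == rna[g]}
    else:
        both = set(prot) & set(rna)
    triple = both & set(cnv_changed)
    chrom_of = {a.gene: a.chromosome for a in annotation}
    counts = {}
    for g in triple:
        chrom = chrom_of.get(g)
        if chrom is not None:
            counts[chrom] = counts.get(chrom, 0) + 1
    order = {c: i for i, c in enumerate(CHROMOSOMES)}
    tally = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], order[kv[0]])),
        columns=["chromosome", "n_genes"])
    return ConcordantSets(mrna_protein=both, triple=triple, tally=tally)
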