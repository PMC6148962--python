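"""Matching observed peptides against the SAAV database and cohort logic.

An observed peptide evidences a SAAV when its sequence matches a mutant
database entry exactly (optionally after I/L folding, with the same flag
the database was built with).  Cohort specificity then classifies each
distinct event: seen only in the non-metastatic (NM) cohort, only in the
metastatic (MT) cohort, or shared.  Per-protein counts follow occurrence
semantics — every (sample, event) observation counts once — matching the
"No. of SAAVs" convention of published SAAV tables, where one listed site
seen in eight patients counts as eight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .errors import ValidationError
from .saav_db import fold_il

#: Cohort labels understood out of the box; PN = paired adjacent-normal,
#: NM = primary tumour without liver metastasis, MT = primary tumour with
#: liver metastasis, LM = the liver metastasis focus itself.
KNOWN_COHORTS = ("PN", "NM", "MT", "LM")

_ID_COLUMNS = ["sample", "cohort", "peptide", "intensity"]


def _check_id_table(ids: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _ID_COLUMNS if c not in ids.columns]
    if missing:
        raise ValidationError(f"peptide-id table missing columns {missing}")
    if (ids["intensity"] < 0).any():
        raise ValidationError("negative intensity in peptide-id table")
    if (ids["peptide"].str.len() < 7).any():
        raise ValidationError("peptide shorter than 7 residues in id table")
    return ids


def match_peptides(ids: pd.DataFrame, index: pd.DataFrame,
                   il_fold: bool = False):
    """Match identified peptides to mutant database entries.

    Returns ``(observations, detail)``.  ``observations`` holds one row
    per (sample, event) with the summed supporting intensity and peptide
    multiplicity; ``detail`` keeps every supporting peptide row.
    """
    ids = _check_id_table(ids)
    db = index.copy()
    if il_fold:
        db["match_key"] = db["mutant_peptide"].map(fold_il)
        obs_key = ids["peptide"].map(fold_il)
    else:
        db["match_key"] = db["mutant_peptide"]
        obs_key = ids["peptide"]
    merged = ids.assign(match_key=obs_key).merge(
        db[["match_key", "span_id", "site", "accession"]],
        on="match_key", how="inner")
    detail = merged.drop(columns="match_key").reset_index(drop=True)
    if detail.empty:
        observations = pd.DataFrame(columns=[
            "sample", "cohort", "accession", "site", "span_id",
            "intensity", "n_peptides"])
    else:
        observations = (detail
                        .groupby(["sample", "cohort", "accession", "site"],
                                 as_index=False)
                        .agg(span_id=("span_id", "first"),
                             intensity=("intensity", "sum"),
                             n_peptides=("peptide", "nunique")))
    return observations, detail


def count_mutated_peptides(ids: pd.DataFrame, index: pd.DataFrame,
                           il_fold: bool = False) -> pd.DataFrame:
    """Per-sample (mutated, total) distinct peptide counts.

    ``mutated`` counts the distinct observed peptides that match the SAAV
    database; ``total`` counts all distinct observed peptides.
    """
    ids = _check_id_table(ids)
    mutant_set = (set(map(fold_il, index["mutant_peptide"])) if il_fold
                  else set(index["mutant_peptide"]))
    key = ids["peptide"].map(fold_il) if il_fold else ids["peptide"]
    flagged = ids.assign(_mut=key.isin(mutant_set))
    out = (flagged.groupby(["sample", "cohort"], as_index=False)
           .agg(total_count=("peptide", "nunique")))
    mutated = (flagged[flagged["_mut"]]
               .groupby("sample")["peptide"].nunique())
    out["mutated_count"] = out["sample"].map(mutated).fillna(0).astype(int)
    return out[["sample", "cohort", "mutated_count", "total_count"]]


@dataclass
class SpecificityResult:
    """Cohort-specificity classification of observed SAAV events."""

    event_class: pd.DataFrame     # accession, site, class
    per_protein: pd.DataFrame     # class, accession, n_saavs
    totals: dict = field(default_factory=dict)


def classify_specificity(observations: pd.DataFrame,
                         cohorts: tuple[str, str] = ("NM", "MT"),
                         known_cohorts=KNOWN_COHORTS) -> SpecificityResult:
    """Classify each observed event by its cohort footprint.

    An event is ``{C}-specific`` when observed in at least one sample of
    cohort C and in no sample of the other contrast cohort; ``shared``
    when observed in both.  Observations from cohorts outside the contrast
    (e.g. PN) are tracked upstream but excluded here.  Per-protein counts
    sum occurrences: each (sample, event) observation contributes one.
    """
    unknown = set(observations["cohort"]) - set(known_cohorts)
    if unknown:
        raise ValidationError(f"unknown cohort label(s): {sorted(unknown)}")
    a, b = cohorts
    obs = observations[observations["cohort"].isin(cohorts)]
    obs = obs.drop_duplicates(subset=["sample", "accession", "site"])

    def label(group: pd.Series) -> str:
        seen = set(group)
        if seen == {a, b}:
            return "shared"
        return f"{seen.pop()}-specific"

    if obs.empty:
        event_class = pd.DataFrame(columns=["accession", "site", "class"])
    else:
        event_class = (obs.groupby(["accession", "site"])["cohort"]
                       .apply(label).rename("class").reset_index())
    tagged = obs.merge(event_class, on=["accession", "site"], how="left")
    per_protein = (tagged.groupby(["class", "accession"])
                   .size().rename("n_saavs").reset_index()
                   if not tagged.empty else
                   pd.DataFrame(columns=["class", "accession", "n_saavs"]))
    totals = {cls: 0 for cls in (f"{a}-specific", f"{b}-specific", "shared")}
    totals.update(per_protein.groupby("class")["n_saavs"].sum().to_dict())
    return SpecificityResult(event_class=event_class,
                             per_protein=per_protein, totals=totals)


def compare_counts(*groups):
    """Compare per-sample counts between cohorts by rank.

    Two groups: two-sided Wilcoxon rank-sum (Mann-Whitney, mid-ranks,
    exact for small tie-free samples, tie-corrected normal approximation
    otherwise).  Three or more: Kruskal-Wallis.  Degenerate all-identical
    input returns p = 1 with a warning.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValidationError("each group needs >= 2 values")
    flat = [v for g in groups for v in g]
    if len(set(flat)) == 1:
        warnings.warn("all values identical; comparison degenerate",
                      UserWarning, stacklevel=2)
        return 0.0, 1.0
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1],
                                 alternative="two-sided")
    else:
        res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
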