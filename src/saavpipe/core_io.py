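"""Readers and writers for every external format the pipeline touches.

All coordinates are 1-based inclusive end-to-end, matching the peptide span
notation used throughout (``ACC_start_end``).  Writers emit deterministic
column order and never reorder rows; row order is the caller's business so
that diffs stay reproducible.  Missing cells are serialized as empty strings;
``NA``/``NaN`` are accepted on read under the lenient flag because common
quantification exports vary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Valid chromosome labels (human autosomes plus sex chromosomes).
CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

#: Pattern for compact substitution-site notation, e.g. ``D179N``.
SITE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

#: Pattern extracting the accession from a UniProt ``sp|ACC|NAME`` header.
UNIPROT_HEADER_RE = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


# ---------------------------------------------------------------------------
# Domain record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinSeq:
    """A protein entry: accession plus amino-acid sequence.

    The sequence must be non-empty and drawn from the 20 canonical letters
    unless constructed with ``allow_nonstandard`` via :func:`make_protein`.
    """

    accession: str
    sequence: str
    gene: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def make_protein(accession: str, sequence: str, gene: str | None = None,
                 allow_nonstandard: bool = False) -> ProteinSeq:
    """Validated :class:`ProteinSeq` constructor.

    ``allow_nonstandard`` admits U/B/Z/X (selenocysteine and ambiguity
    codes); the default policy rejects them.
    """
    if not sequence:
        raise ValidationError(f"{accession}: empty sequence")
    alphabet = set(CANONICAL_AA) | (set("UBZX") if allow_nonstandard else set())
    bad = sorted(set(sequence) - alphabet)
    if bad:
        raise ValidationError(
            f"{accession}: non-canonical residue(s) {''.join(bad)}")
    return ProteinSeq(accession=accession, sequence=sequence, gene=gene)


@dataclass(frozen=True)
class SaavEvent:
    """One protein-level single-amino-acid substitution with provenance.

    ``position`` is the 1-based residue index in the parent protein;
    ``ref``/``alt`` are single canonical letters and must differ.
    """

    accession: str
    position: int
    ref: str
    alt: str
    sample: str = ""
    cohort: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(
                f"{self.accession}: non-positive position {self.position}")
        for aa, name in ((self.ref, "ref"), (self.alt, "alt")):
            if len(aa) != 1 or aa not in CANONICAL_AA:
                raise ValidationError(
                    f"{self.accession}: {name} residue {aa!r} not canonical")
        if self.ref == self.alt:
            raise ValidationError(
                f"{self.accession}: ref equals alt at {self.position} "
                f"({self.site})")

    @property
    def site(self) -> str:
        """Compact notation, e.g. ``D179N``."""
        return f"{self.ref}{self.position}{self.alt}"


def parse_site(site: str) -> tuple[str, int, str]:
    """Parse compact ``XnY`` site notation into ``(ref, position, alt)``."""
    m = SITE_RE.match(site.replace(" ", ""))
    if not m:
        raise ParseError(f"malformed site notation: {site!r}")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene location: symbol, chromosome and 1-based inclusive span."""

    gene: str
    chromosome: str
    start: int
    end: int
    band: str | None = None

    def __post_init__(self):
        if self.chromosome not in CHROMOSOMES:
            raise ValidationError(f"{self.gene}: bad chromosome "
                                  f"{self.chromosome!r}")
        if self.start > self.end:
            raise ValidationError(
                f"{self.gene}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up for one subject: time (months), event flag, stratum."""

    sample: str
    time: float
    event: int
    group: str = ""

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError(f"{self.sample}: negative time {self.time}")
        if self.event not in (0, 1):
            raise ValidationError(f"{self.sample}: event must be 0/1, "
                                  f"got {self.event}")


@dataclass
class QuantMatrix:
    """Feature x sample abundance table; NaN marks missing.

    ``scale`` is ``"raw"`` (non-negative intensities/RPKM) or ``"log2"``;
    log transformation is applied at most once and the tag enforces it.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self):
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicated feature ids: {list(dups)[:5]}")
        if self.scale == "raw":
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError("raw-scale matrix contains negatives")

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.data.copy(), self.scale)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, uniprot_dialect: bool = False,
               allow_nonstandard: bool = False) -> list[ProteinSeq]:
    """Read a protein FASTA into a list of :class:`ProteinSeq`.

    The accession is the header token before the first whitespace; with
    ``uniprot_dialect`` the ``sp|ACC|NAME`` form is unpacked to ``ACC``.
    Duplicate accessions and non-canonical residues raise.
    """
    proteins: list[ProteinSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if uniprot_dialect:
            m = UNIPROT_HEADER_RE.match(acc)
            if m:
                acc = m.group(1)
        if acc in seen:
            raise ParseError(f"{path}: duplicate accession {acc!r}")
        seen.add(acc)
        try:
            proteins.append(make_protein(acc, str(rec.seq).upper(),
                                         allow_nonstandard=allow_nonstandard))
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return proteins


def write_fasta(proteins: Iterable[ProteinSeq], path) -> None:
    records = [SeqRecord(Seq(p.sequence), id=p.accession, description="")
               for p in proteins]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ["accession", "position", "ref", "alt", "sample", "cohort"]


def read_variant_table(path) -> list[SaavEvent]:
    """Read a TSV of protein-level substitutions.

    Accepts either explicit ``position``/``ref``/``alt`` columns or a
    compact ``site`` column (``D179N``).  Rows with ref == alt or a
    non-positive position raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "accession" not in df.columns:
        raise ParseError(f"{path}: missing 'accession' column")
    events = []
    for i, row in df.iterrows():
        if "site" in df.columns and row.get("site"):
            ref, pos, alt = parse_site(row["site"])
        else:
            try:
                pos = int(row["position"])
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: row {i}: bad position") from exc
            ref, alt = row["ref"], row["alt"]
        try:
            events.append(SaavEvent(
                accession=row["accession"], position=pos, ref=ref, alt=alt,
                sample=row.get("sample", ""), cohort=row.get("cohort", "")))
        except ValidationError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return events


def write_variant_table(events: Sequence[SaavEvent], path) -> None:
    rows = [{"accession": e.accession, "position": e.position, "ref": e.ref,
             "alt": e.alt, "sample": e.sample, "cohort": e.cohort,
             "site": e.site} for e in events]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS + ["site"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quantification matrices
# ---------------------------------------------------------------------------

def read_matrix(path, scale: str = "raw", lenient_na: bool = True) -> QuantMatrix:
    """Read a feature x sample TSV; first column holds feature ids.

    Empty cells are missing.  Under ``lenient_na`` the tokens ``NA``/``NaN``
    are missing too; otherwise any non-numeric cell raises.
    """
    na_values = ["", "NA", "NaN", "nan"] if lenient_na else [""]
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=na_values,
                     keep_default_na=False, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise ParseError(f"{path}: duplicated feature ids {list(dups)[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(f"{path}: non-numeric cell {df.iat[r, c]!r} at "
                         f"feature {df.index[r]!r}, sample {df.columns[c]!r}")
    return QuantMatrix(numeric, scale=scale)


def write_matrix(qm: QuantMatrix, path) -> None:
    qm.data.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Copy-number segments (SEG-style TSV)
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ["sample", "chromosome", "start", "end", "value"]


def read_segments(path) -> pd.DataFrame:
    """Read SEG-style copy-number segments.

    Columns: sample, chromosome, start, end, value (log-ratio or state);
    coordinates 1-based inclusive; no NaN allowed anywhere.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chromosome": str})
    missing = [c for c in _SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df[_SEG_COLUMNS].copy()
    if df.isna().to_numpy().any():
        raise ParseError(f"{path}: NaN values in segment table")
    if (df["sample"].str.len() == 0).any():
        raise ParseError(f"{path}: empty sample id")
    bad = df[df["start"] > df["end"]]
    if len(bad):
        row = bad.iloc[0]
        raise ParseError(f"{path}: segment start > end "
                         f"({row['chromosome']}:{row['start']}-{row['end']})")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_segments(segments: pd.DataFrame, path) -> None:
    segments[_SEG_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Survival tables
# ---------------------------------------------------------------------------

def read_survival(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(SurvivalRecord(
                sample=row["sample"], time=float(row["time"]),
                event=int(row["event"]),
                group=str(row["group"]) if "group" in df.columns else ""))
        except ValidationError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return records


def write_survival(records: Sequence[SurvivalRecord], path) -> None:
    rows = [{"sample": r.sample, "time": r.time, "event": r.event,
             "group": r.group} for r in records]
    pd.DataFrame(rows, columns=["sample", "time", "event", "group"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_annotation(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str,
                                            "band": str})
    records = []
    for i, row in df.iterrows():
        try:
            records.append(GeneAnnotation(
                gene=row["gene"], chromosome=row["chromosome"],
                start=int(row["start"]), end=int(row["end"]),
                band=row.get("band") or None))
        except (ValidationError, KeyError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return records


def write_annotation(annotation: Sequence[GeneAnnotation], path) -> None:
    rows = [{"gene": a.gene, "chromosome": a.chromosome, "start": a.start,
             "end": a.end, "band": a.band or ""} for a in annotation]
    pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end",
                                "band"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Schema validation (CLI `validate`)
# ---------------------------------------------------------------------------

_READERS = {
    "fasta": read_fasta,
    "variants": read_variant_table,
    "matrix": read_matrix,
    "segments": read_segments,
    "survival": read_survival,
    "annotation": read_annotation,
}


def validate_file(path, kind: str) -> int:
    """Check a file against its schema; return the record count.

    ``kind`` is one of fasta, variants, matrix, segments, survival,
    annotation.  Raises :class:`ParseError` on any violation.
    """
    if kind not in _READERS:
        raise ValueError(f"unknown input kind {kind!r}; "
                         f"choose from {sorted(_READERS)}")
    if not Path(path).exists():
        raise ParseError(f"{path}: file not found")
    result = _READERS[kind](path)
    if isinstance(result, QuantMatrix):
        return len(result.data)
    if isinstance(result, pd.DataFrame):
        return len(result)
    return len(result)
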