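"""Sequence and study-metadata I/O: FASTA records, marker registry,
DMS coordinate conversion, GC screening, and marker concatenation.

FASTA header grammar
--------------------
Every record id is ``sample_id|site_id|marker`` (pipe-separated, three
fields). The description after the first whitespace is ignored. Example::

    >sp1_i03|site12|rbcL population sample
    ATGTCACCACAAACAGAGACTAAAGCAAGT...

Markers
-------
Five barcode loci are registered: the plastid coding regions rbcL, matK and
ycf, the plastid intergenic spacer trnH-psbA, and the nuclear spacer ITS2.
Combination labels (core, coding, non-coding, cpDNA, total) name fixed marker
sets used for concatenation and for combination-level taxonomic summaries.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .exceptions import AlphabetError, DomainError, FastaParseError

# IUPAC nucleotide codes, N, and the gap character.
NUCLEOTIDE_ALPHABET = frozenset("ACGTURYSWKMBDHVN-")

#: marker -> (genome, coding)
MARKERS = {
    "rbcL": ("plastid", True),
    "matK": ("plastid", True),
    "ycf": ("plastid", True),
    "trnH-psbA": ("plastid", False),
    "ITS2": ("nuclear", False),
}

#: combination label -> member markers (canonical order: alphabetical,
#: case-insensitive — the concatenation order used throughout).
COMBINATIONS = {
    "core": ("matK", "rbcL"),
    "coding": ("matK", "rbcL", "ycf"),
    "non-coding": ("ITS2", "trnH-psbA"),
    "cpDNA": ("matK", "rbcL", "trnH-psbA", "ycf"),
    "total": ("ITS2", "matK", "rbcL", "trnH-psbA", "ycf"),
}


def registered_marker_labels():
    """All accepted values for ``SequenceRecord.marker``."""
    return tuple(MARKERS) + tuple(COMBINATIONS)


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence tied to a sample, a collection site and a marker."""

    sample_id: str
    site_id: str
    marker: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise AlphabetError(f"{self.sample_id}: empty sequence")
        if self.marker not in MARKERS and self.marker not in COMBINATIONS:
            raise FastaParseError(
                f"{self.sample_id}: unknown marker {self.marker!r}"
            )
        bad = set(self.seq.upper()) - NUCLEOTIDE_ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.sample_id}: illegal characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "seq", self.seq.upper())


def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-FASTA file into :class:`SequenceRecord` objects.

    Raises :class:`FastaParseError` naming the offending header when the
    ``sample|site|marker`` grammar is violated, and :class:`AlphabetError`
    on characters outside the IUPAC nucleotide alphabet.
    """
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        fields = rec.id.split("|")
        if len(fields) != 3 or not all(fields):
            raise FastaParseError(
                f"{path}: record {i} header {rec.id!r} does not match "
                "'sample_id|site_id|marker'"
            )
        records.append(SequenceRecord(fields[0], fields[1], fields[2], str(rec.seq)))
    return records


def write_fasta(records, path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    bio = [
        _BioSeqRecord(
            Seq(r.seq), id=f"{r.sample_id}|{r.site_id}|{r.marker}", description=""
        )
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def dms_to_decimal(degrees, minutes, seconds, sign=1) -> float:
    """Convert degree/minute/second to signed decimal degrees."""
    if not (0 <= minutes < 60):
        raise DomainError(f"minutes out of range: {minutes}")
    if not (0 <= seconds < 60):
        raise DomainError(f"seconds out of range: {seconds}")
    return sign * (degrees + minutes / 60.0 + seconds / 3600.0)


def decimal_to_dms(dd):
    """Inverse of :func:`dms_to_decimal`; returns (degrees, minutes, seconds, sign)."""
    sign = -1 if dd < 0 else 1
    dd = abs(dd)
    degrees = int(dd)
    rem = (dd - degrees) * 60.0
    minutes = int(rem)
    seconds = (rem - minutes) * 60.0
    return degrees, minutes, seconds, sign

_DMS_RE = re.compile(
    r"""^\s*(?P<d>\d+)\s*[°ᶱdD]\s*(?P<m>\d+)\s*[′'ʹmM]\s*
        (?P<s>\d+(?:\.\d+)?)\s*[″"ʺsS]?\s*(?P<hemi>[NSEW]?)\s*$""",
    re.VERBOSE,
)


def parse_dms(text) -> float:
    """Parse a DMS string like ``50° 49′ 26.511″`` to decimal degrees.

    S/W hemisphere suffixes negate; raises :class:`DomainError` when the
    string does not parse or minutes/seconds are out of range.
    """
    m = _DMS_RE.match(str(text))
    if not m:
        raise DomainError(f"unparseable DMS string: {text!r}")
    sign = -1 if m.group("hemi") in ("S", "W") else 1
    return dms_to_decimal(
        int(m.group("d")), int(m.group("m")), float(m.group("s")), sign
    )


def read_sample_table(path=None) -> pd.DataFrame:
    """Read the sampling-site metadata table.

    Expects columns ``site_no, province, site_name, lon_dms, lat_dms``; adds
    decimal-degree columns ``lon_dd, lat_dd``. A DMS token that does not
    parse (the packaged table keeps one malformed seconds field verbatim)
    yields NaN with a warning rather than discarding the site row. With no
    argument, reads the packaged table of 26 collection sites.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "sampling_sites.csv"
    df = pd.read_csv(path)
    required = {"site_no", "province", "site_name", "lon_dms", "lat_dms"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"sample table missing columns: {sorted(missing)}")
    if df["site_no"].duplicated().any():
        raise DomainError("duplicate site_no in sample table")

    def _safe(text, limit):
        try:
            dd = parse_dms(text)
        except DomainError as exc:
            warnings.warn(f"sample table: {exc}", stacklevel=2)
            return math.nan
        if not (-limit <= dd <= limit):
            warnings.warn(f"coordinate out of range: {text!r}", stacklevel=2)
            return math.nan
        return dd

    df["lon_dd"] = [_safe(t, 180.0) for t in df["lon_dms"]]
    df["lat_dd"] = [_safe(t, 90.0) for t in df["lat_dms"]]
    return df


def load_synonym_groups(path=None) -> dict[str, str]:
    """Load the species -> species-group mapping (CSV: species,group).

    The packaged default holds the six-name *S. europaea* complex treated as
    indistinguishable at barcode resolution. Each species may belong to at
    most one group.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "synonym_groups.csv"
    df = pd.read_csv(path)
    if not {"species", "group"} <= set(df.columns):
        raise DomainError("synonym-group file needs 'species' and 'group' columns")
    if df["species"].duplicated().any():
        dupes = df.loc[df["species"].duplicated(), "species"].tolist()
        raise DomainError(f"species mapped to multiple groups: {dupes}")
    return dict(zip(df["species"], df["group"]))


def gc_content(seq) -> float:
    """Fraction (G+C)/(A+C+G+T); gaps, N and ambiguity codes are excluded
    from both numerator and denominator."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    total = gc + s.count("A") + s.count("T")
    if total == 0:
        raise DomainError("GC content undefined: no unambiguous bases")
    return gc / total


def flag_high_gc(records, threshold=0.65):
    """Return records whose GC content strictly exceeds ``threshold``.

    The screening rule treats GC content *above* 65% as high (candidates for
    cloning before sequencing); the boundary value is not flagged.
    """
    if not (0 < threshold < 1):
        raise DomainError(f"threshold must be in (0,1): {threshold}")
    return [r for r in records if gc_content(r.seq) > threshold]


def concatenate_markers(records, combination_label):
    """Concatenate per-sample marker sequences into one record per sample.

    Markers are joined in the registry's canonical (alphabetical) order.
    Samples missing any member marker are excluded and listed in the report.

    Returns ``(concatenated_records, excluded_report)`` where the report maps
    sample_id -> sorted list of missing markers.
    """
    if combination_label not in COMBINATIONS:
        raise DomainError(f"unknown combination label: {combination_label!r}")
    members = COMBINATIONS[combination_label]
    by_sample: dict[str, dict[str, SequenceRecord]] = {}
    site_of: dict[str, str] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, {})[r.marker] = r
        site_of.setdefault(r.sample_id, r.site_id)
    out, excluded = [], {}
    for sample_id in sorted(by_sample):
        have = by_sample[sample_id]
        missing = [m for m in members if m not in have]
        if missing:
            excluded[sample_id] = missing
            continue
        seq = "".join(have[m].seq for m in members)
        out.append(
            SequenceRecord(sample_id, site_of[sample_id], combination_label, seq)
        )
    return out, excluded
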