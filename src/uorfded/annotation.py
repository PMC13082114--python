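"""Transcript-anchored feature annotations for uORF translation analysis.

Every coordinate in this package lives in transcript space: position 0 is the
first nucleotide of the mature mRNA and spans are 0-based, half-open, exactly
as in BED.  A transcript is partitioned into a 5'UTR, a main ORF (mORF) and a
3'UTR; upstream ORFs (uORFs) are additional spans inside the 5'UTR with a
start-codon class of either AUG or near-cognate (NCC).  Genome-to-transcript
lifting is deliberately out of scope, which removes strand handling from the
core model.

uORF compilations from different sources (ribosome-profiling evidence,
reporter screens, conservation) are merged by exact span identity: two
records on the same transcript with the same span are the same uORF and the
merged record carries the union of source tags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Span",
    "TranscriptModel",
    "UORFRecord",
    "UORFCompilation",
    "AnnotationError",
    "NCC_DEFAULT",
    "classify_start_codon",
    "read_transcript_features",
    "write_transcript_features",
    "read_uorf_bed",
    "write_uorf_bed",
    "merge_uorf_compilations",
    "validate_annotation",
]

#: Near-cognate start codons recognised by default.  AAG and AGG are excluded
#: because AAG is the canonical "dead" start-codon substitution used to build
#: uORF-less mutant reporters, so it must classify as NONFUNCTIONAL.
NCC_DEFAULT = frozenset({"CTG", "GTG", "TTG", "ACG", "ATA", "ATT", "ATC"})

_VALID_NT = set("ACGT")


class AnnotationError(ValueError):
    """Raised for malformed or internally inconsistent annotation inputs."""


@dataclass(frozen=True, order=True)
class Span:
    """A 0-based, half-open interval ``[start, end)`` on a transcript."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise AnnotationError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class TranscriptModel:
    """5'UTR / mORF / 3'UTR spans of one transcript.

    Invariants: the three spans tile ``[utr5.start, utr3.end)`` contiguously,
    the mORF length is a positive multiple of 3 and everything fits inside
    ``length``.
    """

    transcript_id: str
    length: int
    utr5: Span
    morf: Span
    utr3: Span

    def problems(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        p = []
        t = self.transcript_id
        if not (0 <= self.utr5.start <= self.utr5.end == self.morf.start):
            p.append(f"{t}: 5'UTR [{self.utr5.start},{self.utr5.end}) does not abut mORF start {self.morf.start}")
        if not (self.morf.end == self.utr3.start <= self.utr3.end <= self.length):
            p.append(f"{t}: mORF/3'UTR spans inconsistent with transcript length {self.length}")
        morf_len = len(self.morf)
        if morf_len <= 0 or morf_len % 3 != 0:
            p.append(f"{t}: mORF length {morf_len} is not a positive multiple of 3")
        return p

    def validate(self) -> "TranscriptModel":
        problems = self.problems()
        if problems:
            raise AnnotationError("; ".join(problems))
        return self


@dataclass(frozen=True)
class UORFRecord:
    """One uORF: a span inside a transcript's 5'UTR plus provenance.

    ``span`` excludes the stop codon by convention (see ``read_uorf_bed`` for
    importing external BEDs that include it).  ``start_class`` is "AUG" or
    "NCC"; dead start codons never form records.
    """

    uorf_id: str
    transcript_id: str
    span: Span
    start_class: str = "AUG"
    sources: frozenset[str] = frozenset()

    def key(self) -> tuple[str, int, int]:
        return (self.transcript_id, self.span.start, self.span.end)


@dataclass(frozen=True)
class UORFCompilation:
    """A deduplicated, sorted collection of uORF records."""

    records: tuple[UORFRecord, ...] = ()
    provenance: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_transcript(self) -> dict[str, list[UORFRecord]]:
        out: dict[str, list[UORFRecord]] = {}
        for r in self.records:
            out.setdefault(r.transcript_id, []).append(r)
        return out


def classify_start_codon(codon: str, ncc_set: frozenset[str] = NCC_DEFAULT) -> str:
    """Classify a 3-nt codon as "AUG", "NCC" or "NONFUNCTIONAL".

    U is accepted as a synonym for T.  The near-cognate set is configurable;
    the default deliberately excludes AAG/AGG so that the standard dead-start
    mutation (AUG→AAG) is classified as non-functional.
    """
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or not set(c) <= _VALID_NT:
        raise AnnotationError(f"not a nucleotide codon: {codon!r}")
    if c == "ATG":
        return "AUG"
    if c in {s.upper().replace("U", "T") for s in ncc_set}:
        return "NCC"
    return "NONFUNCTIONAL"


_FEATURE_KINDS = ("utr5", "morf", "utr3")


def read_transcript_features(path: str | Path) -> dict[str, TranscriptModel]:
    """Read transcript feature spans from a BED-like file.

    Expected columns (tab-separated, BED6-compatible): transcript_id, start,
    end, name, [score, strand]; ``name`` is ``<transcript_id>|<kind>`` with
    kind one of utr5/morf/utr3.  Each transcript must contribute all three
    rows.  Transcript length is taken as ``utr3.end``.
    """
    spans: dict[str, dict[str, Span]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationError(f"{path}:{lineno}: expected >=4 BED columns, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if "|" not in name:
                raise AnnotationError(f"{path}:{lineno}: name {name!r} is not '<transcript_id>|<kind>'")
            tid, kind = name.rsplit("|", 1)
            if kind not in _FEATURE_KINDS:
                raise AnnotationError(f"{path}:{lineno}: unknown feature kind {kind!r}")
            if tid != chrom:
                raise AnnotationError(f"{path}:{lineno}: name transcript {tid!r} != chrom {chrom!r}")
            per = spans.setdefault(tid, {})
            if kind in per:
                raise AnnotationError(f"{path}:{lineno}: duplicate {kind} row for {tid}")
            per[kind] = Span(start, end)
    out: dict[str, TranscriptModel] = {}
    for tid, per in spans.items():
        missing = [k for k in _FEATURE_KINDS if k not in per]
        if missing:
            raise AnnotationError(f"{tid}: missing feature rows {missing}")
        tm = TranscriptModel(tid, per["utr3"].end, per["utr5"], per["morf"], per["utr3"])
        tm.validate()
        out[tid] = tm
    return out


def write_transcript_features(transcripts: Mapping[str, TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(transcripts):
            tm = transcripts[tid]
            for kind in _FEATURE_KINDS:
                span: Span = getattr(tm, kind)
                fh.write(f"{tid}\t{span.start}\t{span.end}\t{tid}|{kind}\t0\t+\n")


def read_uorf_bed(
    path: str | Path,
    source: str | None = None,
    span_includes_stop: bool = False,
) -> UORFCompilation:
    """Read one uORF compilation from BED6.

    ``name`` is ``<uorf_id>|<start_class>`` (start_class optional, default
    AUG).  With ``span_includes_stop`` the imported span is trimmed by 3 nt
    so internal records uniformly exclude the stop codon — compilations in
    the wild differ on this and silently mixing conventions would create
    off-by-three duplicates at merge time.
    """
    records = []
    src = frozenset() if source is None else frozenset({source})
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if span_includes_stop:
                end -= 3
            uorf_id, _, start_class = name.partition("|")
            records.append(
                UORFRecord(uorf_id, chrom, Span(start, end), start_class or "AUG", src)
            )
    prov = (source,) if source else ()
    return UORFCompilation(tuple(records), prov)


def write_uorf_bed(comp: UORFCompilation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in comp.records:
            fh.write(
                f"{r.transcript_id}\t{r.span.start}\t{r.span.end}\t{r.uorf_id}|{r.start_class}\t0\t+\n"
            )


def merge_uorf_compilations(compilations: Sequence[UORFCompilation]) -> UORFCompilation:
    """Union of compilations with exact-duplicate records collapsed.

    Two records are the same uORF iff they share (transcript_id, span); the
    surviving record keeps the first-seen id and start class and the union of
    source tags.  Partially overlapping records are distinct uORFs and both
    kept.  The result is sorted by (transcript_id, span).
    """
    merged: dict[tuple[str, int, int], UORFRecord] = {}
    provenance: list[str] = []
    for comp in compilations:
        for p in comp.provenance:
            if p not in provenance:
                provenance.append(p)
        for rec in comp.records:
            key = rec.key()
            if key in merged:
                old = merged[key]
                merged[key] = replace(old, sources=old.sources | rec.sources)
            else:
                merged[key] = rec
    records = tuple(sorted(merged.values(), key=UORFRecord.key))
    return UORFCompilation(records, tuple(provenance))


def validate_annotation(
    transcripts: Mapping[str, TranscriptModel],
    uorfs: UORFCompilation,
    min_codons: int = 2,
    allow_morf_overlap: bool = False,
) -> list[str]:
    """Report every invariant violation in an annotation set (report-only).

    Checks, per uORF: the transcript resolves; the span lies within the
    5'UTR and (unless ``allow_morf_overlap``) ends at or before the mORF
    start; the span length is a multiple of 3 and at least ``min_codons``
    codons (stop codon excluded from the span by convention); no duplicate
    (transcript, span) pairs.  Transcript-level invariants are re-checked.
    """
    report: list[str] = []
    for tid, tm in transcripts.items():
        report.extend(tm.problems())
    seen: set[tuple[str, int, int]] = set()
    for rec in uorfs:
        tm = transcripts.get(rec.transcript_id)
        if tm is None:
            report.append(f"{rec.uorf_id}: unknown transcript {rec.transcript_id!r}")
            continue
        key = rec.key()
        if key in seen:
            report.append(f"{rec.uorf_id}: duplicate record for {key}")
        seen.add(key)
        n = len(rec.span)
        if n % 3 != 0 or n < 3 * min_codons:
            report.append(
                f"{rec.uorf_id}: span length {n} not a multiple of 3 of >= {min_codons} codons"
            )
        if rec.span.start < tm.utr5.start or rec.span.start >= tm.morf.start:
            report.append(f"{rec.uorf_id}: start {rec.span.start} outside the 5'UTR of {rec.transcript_id}")
        elif rec.span.end > tm.morf.start and not allow_morf_overlap:
            report.append(
                f"{rec.uorf_id}: span extends past mORF start {tm.morf.start} of {rec.transcript_id}"
            )
        if rec.start_class not in ("AUG", "NCC"):
            report.append(f"{rec.uorf_id}: start_class {rec.start_class!r} is not AUG/NCC")
    return report
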