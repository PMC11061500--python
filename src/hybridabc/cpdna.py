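"""Maternal direction of hybridization from chloroplast haplotypes.

Chloroplasts are maternally inherited in grasses, so fixed differences
between the two parental haplotype classes identify which species mothered
each hybrid.  Given an alignment with labelled parental accessions,
:func:`find_diagnostics` extracts the diagnostic substitutions and indel
events (a multi-base-pair insertion/deletion counts as a single event), and
:func:`classify_maternal` assigns each remaining sequence to a parental
class by majority vote over the scorable events, with a per-event agreement
vector for audit.  Input must be pre-aligned (gap character ``-``); two
concatenated markers can be scored as one alignment via
:func:`concat_alignments`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "HaplotypeAlignment",
    "DiagnosticSet",
    "read_alignment",
    "concat_alignments",
    "find_diagnostics",
    "classify_maternal",
    "summarize_directions",
]

_ALPHABET = set("ACGTN-")
_BASES = set("ACGT")


@dataclass(frozen=True)
class HaplotypeAlignment:
    """Aligned haplotype sequences of uniform length (A/C/G/T/N/-)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
        for sid, seq in self.sequences.items():
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"sequence {sid!r} contains invalid symbols {sorted(bad)}")
        object.__setattr__(
            self, "sequences", {k: v.upper() for k, v in self.sequences.items()}
        )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def column(self, j: int, ids) -> list[str]:
        return [self.sequences[i][j] for i in ids]


def read_alignment(path) -> HaplotypeAlignment:
    """Read an aligned FASTA file."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return HaplotypeAlignment(seqs)


def concat_alignments(*alignments: HaplotypeAlignment) -> tuple[HaplotypeAlignment, list[int]]:
    """Concatenate marker alignments sharing the same ids into one partition.

    Returns the combined alignment and the start offset of each input marker
    in the concatenated coordinate system.
    """
    ids = set(alignments[0].ids)
    for aln in alignments[1:]:
        if set(aln.ids) != ids:
            raise ValueError("alignments to concatenate must share sequence ids")
    offsets, pos = [], 0
    for aln in alignments:
        offsets.append(pos)
        pos += aln.length
    combined = {
        sid: "".join(aln.sequences[sid] for aln in alignments) for sid in alignments[0].ids
    }
    return HaplotypeAlignment(combined), offsets


@dataclass(frozen=True)
class DiagnosticSet:
    """Fixed differences between two parental haplotype classes.

    ``snp_sites`` holds (column, class-A allele, class-B allele); each indel
    event is a maximal run of columns gapped in exactly one class, recorded
    as (start column, length, class carrying the bases).
    """

    snp_sites: tuple[tuple[int, str, str], ...]
    indel_events: tuple[tuple[int, int, str], ...]  # (start, length, present_in)
    label_a: str = "A"
    label_b: str = "B"
    skipped_polymorphic: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        for col, a, b in self.snp_sites:
            if a == b:
                raise ValueError(f"diagnostic site {col} has identical alleles")
        for start, _, present_in in self.indel_events:
            if present_in not in (self.label_a, self.label_b):
                raise ValueError(
                    f"indel at {start}: carrier {present_in!r} is not a class label"
                )
        spans = sorted(
            [(c, c + 1) for c, _, _ in self.snp_sites]
            + [(s, s + ln) for s, ln, _ in self.indel_events]
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("diagnostic events overlap")

    @property
    def n_events(self) -> int:
        return len(self.snp_sites) + len(self.indel_events)


def find_diagnostics(
    aln: HaplotypeAlignment, class_a_ids, class_b_ids,
    label_a: str = "A", label_b: str = "B",
) -> DiagnosticSet:
    """Extract fixed diagnostic differences between two parental classes.

    A substitution site requires every class-A sequence to share one base and
    every class-B sequence a different base, with no gaps or N in either
    class at that column; columns polymorphic within a class are skipped
    (counted in ``skipped_polymorphic``).  Indel events are maximal runs of
    columns where one class is entirely gapped and the other entirely based;
    a 4 bp indel is one event of length 4.  Symmetric under swapping class
    labels (alleles flip, sites do not).
    """
    class_a_ids, class_b_ids = list(class_a_ids), list(class_b_ids)
    if not class_a_ids or not class_b_ids:
        raise ValueError("each parental class needs at least one sequence")
    for sid in class_a_ids + class_b_ids:
        if sid not in aln.sequences:
            raise ValueError(f"sequence {sid!r} not in the alignment")

    snp_sites = []
    skipped = 0
    gap_state = []  # per column: "A" bases/B gapped, "B", or None
    for j in range(aln.length):
        col_a = set(aln.column(j, class_a_ids))
        col_b = set(aln.column(j, class_b_ids))
        if col_a == {"-"} and col_b <= _BASES and len(col_b) >= 1:
            gap_state.append(label_b)
            continue
        if col_b == {"-"} and col_a <= _BASES and len(col_a) >= 1:
            gap_state.append(label_a)
            continue
        gap_state.append(None)
        if len(col_a) == 1 and len(col_b) == 1:
            a, b = next(iter(col_a)), next(iter(col_b))
            if a in _BASES and b in _BASES and a != b:
                snp_sites.append((j, a, b))
        elif (col_a | col_b) <= _BASES and len(col_a | col_b) > 1:
            skipped += 1  # would-be site, polymorphic within a class

    indel_events = []
    j = 0
    while j < aln.length:
        state = gap_state[j]
        if state is None:
            j += 1
            continue
        start = j
        while j < aln.length and gap_state[j] == state:
            j += 1
        indel_events.append((start, j - start, state))

    return DiagnosticSet(tuple(snp_sites), tuple(indel_events), label_a, label_b, skipped)


def classify_maternal(
    seq: str, diag: DiagnosticSet, min_sites: int = 2
) -> tuple[str, list[tuple[str, str]]]:
    """Assign a sequence to a parental class by majority vote over events.

    Each diagnostic substitution contributes one vote when the query carries
    either class allele; an indel event contributes one vote when the query
    is entirely gapped (vote for the gapped class) or entirely based (vote
    for the carrier class) across its span.  Gap/N at a substitution site or
    a mixed indel span make the event unscorable — it counts against neither
    class.  Returns ``(label, agreement)`` where ``label`` is the class-A
    label, the class-B label, or ``"ambiguous"`` (tie, or fewer than
    ``min_sites`` scorable events), and ``agreement`` lists one
    ``(event, vote)`` pair per diagnostic event for audit.
    """
    seq = seq.upper()
    votes = {diag.label_a: 0, diag.label_b: 0}
    agreement: list[tuple[str, str]] = []
    for col, a, b in diag.snp_sites:
        ch = seq[col]
        if ch == a:
            votes[diag.label_a] += 1
            vote = diag.label_a
        elif ch == b:
            votes[diag.label_b] += 1
            vote = diag.label_b
        else:
            vote = "unscorable"
        agreement.append((f"snp@{col}", vote))
    for start, length, present_in in diag.indel_events:
        other = diag.label_b if present_in == diag.label_a else diag.label_a
        span = seq[start: start + length]
        if set(span) == {"-"}:
            votes[other] += 1
            vote = other
        elif set(span) <= _BASES:
            votes[present_in] += 1
            vote = present_in
        else:
            vote = "unscorable"
        agreement.append((f"indel@{start}+{length}", vote))
    scorable = votes[diag.label_a] + votes[diag.label_b]
    if scorable < min_sites or votes[diag.label_a] == votes[diag.label_b]:
        return "ambiguous", agreement
    label = diag.label_a if votes[diag.label_a] > votes[diag.label_b] else diag.label_b
    return label, agreement


def summarize_directions(
    labels: dict[str, str], locality: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tabulate maternal-direction calls per locality and overall.

    ``labels`` maps individual id to its maternal call; ``locality`` maps
    individual id to a locality name (individuals without one are grouped
    under ``"unknown"``).  Returns one row per locality plus a ``TOTAL``
    row, with one count column per observed call label.
    """
    if not labels:
        return pd.DataFrame(columns=["locality"])
    locality = locality or {}
    df = pd.DataFrame(
        {
            "individual_id": list(labels),
            "label": [labels[i] for i in labels],
            "locality": [locality.get(i, "unknown") for i in labels],
        }
    )
    counts = (
        df.groupby(["locality", "label"]).size().unstack(fill_value=0).reset_index()
    )
    total = counts.drop(columns="locality").sum()
    total["locality"] = "TOTAL"
    counts = pd.concat([counts, total.to_frame().T], ignore_index=True)
    counts.columns.name = None
    return counts
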