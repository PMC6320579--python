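"""Read processing: trimming, proper-pair filtering, amplicon assignment, coverage.

Two fragment representations coexist:

* :class:`AlignedFragment` — one mapped read pair as an explicit record, used
  for SAM ingestion and small-scale tests.
* :class:`FragmentBatch` — a dense per-amplicon matrix of read bases with
  uniform geometry (all fragments share the amplicon's outer span), produced
  by the simulator and by grouping exact-span fragments.  Pileup and coverage
  operate on either.

Bases are encoded A=0 C=1 G=2 T=3 throughout; N and other ambiguity codes are
mapped to 4 and ignored by the pileup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from amplicall.panel import Amplicon, Panel

logger = logging.getLogger(__name__)

BASES = "ACGT"
N_CODE = 4

# Reads are hard-trimmed at 80 bp from the 5' sequencing end: the 3' tail
# carries most sequencing error, and 2x80 bp on <=157 bp amplicons leaves a
# mate overlap of at most 3 bp.
DEFAULT_TRIM = 80
# Fragments with insert size <= 60 bp are treated as primer-dimer artefacts.
MIN_INSERT_SIZE = 60
# Both fragment ends must match an amplicon's outer coordinates within this
# many bp for the fragment to be assigned (off-target removal).
DEFAULT_ASSIGN_TOLERANCE = 5

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode_bases(seq: str) -> np.ndarray:
    """Encode a base string to uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    lut = np.frombuffer((BASES + "N").encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignedFragment:
    """A read pair as a mapped fragment.

    Mate sequences are stored in *genomic* (forward) orientation, as in
    SAM/BAM; ``r1`` is the forward-strand mate starting at ``frag_start`` and
    ``r2`` the reverse-strand mate ending at ``frag_end``.
    """

    chrom: str
    frag_start: int
    frag_end: int
    proper_pair: bool
    insert_size: int
    r1_start: int
    r1_seq: str
    r2_start: int
    r2_seq: str
    r1_qual: str | None = None
    r2_qual: str | None = None
    sample: str = ""
    replicate: int = 0
    assigned_amplicon: str | None = None

    @property
    def r1_end(self) -> int:
        return self.r1_start + len(self.r1_seq)

    @property
    def r2_end(self) -> int:
        return self.r2_start + len(self.r2_seq)


@dataclass
class FragmentBatch:
    """All fragments of one (sample, replicate, amplicon) as dense matrices.

    ``r1`` holds the forward mates as an (n, l1) base-code matrix anchored at
    ``start``; ``r2`` holds the reverse mates anchored so that they *end* at
    ``end`` (both in genomic orientation).  Uniform geometry is what makes
    vectorised pileup cheap.
    """

    amplicon_id: str
    chrom: str
    start: int
    end: int
    r1: np.ndarray
    r2: np.ndarray
    sample: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.r1.shape[0] != self.r2.shape[0]:
            raise ValueError("mate matrices must have equal row counts")

    @property
    def n(self) -> int:
        return self.r1.shape[0]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def r2_start(self) -> int:
        return self.end - self.r2.shape[1]

    def trimmed(self, limit: int = DEFAULT_TRIM) -> "FragmentBatch":
        """Keep the first ``limit`` bases from each mate's 5' sequencing end.

        For the reverse mate the 5' end is the genomic right end, so trimming
        keeps the last ``limit`` genomic columns.
        """
        l1 = min(limit, self.r1.shape[1])
        l2 = min(limit, self.r2.shape[1])
        return replace(self, r1=self.r1[:, :l1], r2=self.r2[:, -l2:])

    def to_fragments(self) -> list[AlignedFragment]:
        frags = []
        for i in range(self.n):
            frags.append(
                AlignedFragment(
                    chrom=self.chrom,
                    frag_start=self.start,
                    frag_end=self.end,
                    proper_pair=True,
                    insert_size=self.length,
                    r1_start=self.start,
                    r1_seq=decode_bases(self.r1[i]),
                    r2_start=self.r2_start,
                    r2_seq=decode_bases(self.r2[i]),
                    sample=self.sample,
                    replicate=self.replicate,
                    assigned_amplicon=self.amplicon_id,
                )
            )
        return frags


def trim_read(seq: str, qual: str | None = None, limit: int = DEFAULT_TRIM, reverse: bool = False):
    """Retain the first ``min(len, limit)`` bases from the 5' sequencing end.

    ``reverse=True`` means the stored sequence is in genomic orientation for a
    reverse-strand read, whose 5' end is the genomic right end.
    """
    if len(seq) <= limit:
        return seq, qual
    if reverse:
        return seq[-limit:], (qual[-limit:] if qual is not None else None)
    return seq[:limit], (qual[:limit] if qual is not None else None)


def trim_fragment(frag: AlignedFragment, limit: int = DEFAULT_TRIM) -> AlignedFragment:
    """Trim both mates of a fragment at ``limit`` bp (5' anchored per mate)."""
    r1_seq, r1_qual = trim_read(frag.r1_seq, frag.r1_qual, limit, reverse=False)
    r2_seq, r2_qual = trim_read(frag.r2_seq, frag.r2_qual, limit, reverse=True)
    return replace(
        frag,
        r1_seq=r1_seq,
        r1_qual=r1_qual,
        r2_seq=r2_seq,
        r2_qual=r2_qual,
        r2_start=frag.r2_start + (len(frag.r2_seq) - len(r2_seq)),
    )


def filter_fragment(frag: AlignedFragment) -> tuple[bool, str | None]:
    """Keep a fragment iff properly paired with insert size strictly > 60 bp.

    Returns ``(keep, reason)`` where reason is ``not_proper`` or
    ``short_insert`` for dropped fragments.
    """
    if not frag.proper_pair:
        return False, "not_proper"
    if frag.insert_size <= MIN_INSERT_SIZE:
        return False, "short_insert"
    return True, None


def assign_amplicon(
    frag: AlignedFragment | tuple[str, int, int],
    panel: Panel,
    tolerance: int = DEFAULT_ASSIGN_TOLERANCE,
) -> str | None:
    """Assign a fragment to the amplicon whose outer coordinates it matches.

    Both ends must lie within ``tolerance`` bp of the amplicon's outer span;
    fragments matching no amplicon are off-target (``None``).  Ties are broken
    by smallest total end distance, then lexicographic amplicon id, so the
    rule is deterministic on overlapping amplicons.
    """
    if isinstance(frag, AlignedFragment):
        chrom, start, end = frag.chrom, frag.frag_start, frag.frag_end
    else:
        chrom, start, end = frag
    best: tuple[int, str] | None = None
    for a in panel.active:
        if a.chrom != chrom:
            continue
        d = abs(a.outer_start - start) + abs(a.outer_end - end)
        if abs(a.outer_start - start) <= tolerance and abs(a.outer_end - end) <= tolerance:
            key = (d, a.id)
            if best is None or key < best:
                best = key
    return best[1] if best else None


@dataclass
class ProcessedFragments:
    """Outcome of the filter + assign pass over one sample-replicate."""

    by_amplicon: dict[str, list[AlignedFragment]]
    off_target: list[AlignedFragment]
    dropped: dict[str, int]  # reason -> count

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_amplicon.values())

    @property
    def n_retained(self) -> int:
        return self.n_assigned + len(self.off_target)


def process_fragments(
    fragments: Iterable[AlignedFragment],
    panel: Panel,
    tolerance: int = DEFAULT_ASSIGN_TOLERANCE,
) -> ProcessedFragments:
    """Filter fragments and group the retained ones by assigned amplicon."""
    by_amp: dict[str, list[AlignedFragment]] = {}
    off: list[AlignedFragment] = []
    dropped: dict[str, int] = {}
    for frag in fragments:
        keep, reason = filter_fragment(frag)
        if not keep:
            dropped[reason] = dropped.get(reason, 0) + 1
            continue
        amp = assign_amplicon(frag, panel, tolerance)
        if amp is None:
            off.append(frag)
        else:
            frag.assigned_amplicon = amp
            by_amp.setdefault(amp, []).append(frag)
    return ProcessedFragments(by_amplicon=by_amp, off_target=off, dropped=dropped)


@dataclass
class CoverageTable:
    """Per-(sample, replicate, amplicon) read-pair depth with QC summaries."""

    table: "pd.DataFrame"  # columns: sample, replicate, amplicon, depth

    def summary(self, min_depth: int = 100) -> dict:
        depths = self.table["depth"]
        return {
            "median_depth": float(depths.median()) if len(depths) else 0.0,
            "fraction_below_min": float((depths < min_depth).mean()) if len(depths) else 1.0,
            "min_depth_threshold": min_depth,
            "n_entries": int(len(depths)),
        }

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compute_coverage(
    batches: Iterable[FragmentBatch],
    panel: Panel,
) -> CoverageTable:
    """Tabulate assigned read-pair depth per amplicon per sample-replicate.

    Every active amplicon of every observed (sample, replicate) appears in
    the table, with depth 0 where no fragments were assigned; blacklisted
    amplicons are excluded.
    """
    import pandas as pd

    counts: dict[tuple[str, int, str], int] = {}
    seen_sr: set[tuple[str, int]] = set()
    active_ids = {a.id for a in panel.active}
    for b in batches:
        if b.amplicon_id not in active_ids:
            continue
        seen_sr.add((b.sample, b.replicate))
        key = (b.sample, b.replicate, b.amplicon_id)
        counts[key] = counts.get(key, 0) + b.n
    rows = []
    if not seen_sr:
        seen_sr = {("", 0)}
    for sample, rep in sorted(seen_sr):
        for amp_id in sorted(active_ids):
            rows.append(
                {
                    "sample": sample,
                    "replicate": rep,
                    "amplicon": amp_id,
                    "depth": counts.get((sample, rep, amp_id), 0),
                }
            )
    return CoverageTable(table=pd.DataFrame(rows))


def fragments_to_batch(
    fragments: Sequence[AlignedFragment],
    amplicon: Amplicon,
) -> FragmentBatch:
    """Pack exact-span fragments of one amplicon into a dense batch.

    Requires every fragment to span exactly the amplicon's outer coordinates
    with uniform mate lengths (the simulator's geometry); raises otherwise.
    """
    if not fragments:
        return FragmentBatch(
            amplicon_id=amplicon.id,
            chrom=amplicon.chrom,
            start=amplicon.outer_start,
            end=amplicon.outer_end,
            r1=np.zeros((0, 0), dtype=np.uint8),
            r2=np.zeros((0, 0), dtype=np.uint8),
        )
    f0 = fragments[0]
    l1, l2 = len(f0.r1_seq), len(f0.r2_seq)
    for f in fragments:
        if (
            f.frag_start != amplicon.outer_start
            or f.frag_end != amplicon.outer_end
            or len(f.r1_seq) != l1
            or len(f.r2_seq) != l2
        ):
            raise ValueError("fragments do not share the amplicon's exact geometry")
    r1 = np.stack([encode_bases(f.r1_seq) for f in fragments])
    r2 = np.stack([encode_bases(f.r2_seq) for f in fragments])
    return FragmentBatch(
        amplicon_id=amplicon.id,
        chrom=amplicon.chrom,
        start=amplicon.outer_start,
        end=amplicon.outer_end,
        r1=r1,
        r2=r2,
        sample=f0.sample,
        replicate=f0.replicate,
    )


def read_alignments(
    path: str | Path,
    sample: str = "",
    replicate: int = 0,
) -> tuple[list[AlignedFragment], int]:
    """Read coordinate- or name-grouped SAM/BAM into fragments.

    Read pairs are merged into :class:`AlignedFragment` records; unpaired
    orphans are counted, logged and skipped.  Returns ``(fragments,
    n_orphans)``.
    """
    import pysam

    pending: dict[str, "pysam.AlignedSegment"] = {}
    fragments: list[AlignedFragment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (mate, read) if mate.is_read1 else (read, mate)
            frag_start = min(r1.reference_start, r2.reference_start)
            frag_end = max(r1.reference_end, r2.reference_end)
            fragments.append(
                AlignedFragment(
                    chrom=r1.reference_name,
                    frag_start=frag_start,
                    frag_end=frag_end,
                    proper_pair=r1.is_proper_pair and r2.is_proper_pair,
                    insert_size=abs(r1.template_length),
                    r1_start=r1.reference_start,
                    r1_seq=r1.query_sequence,
                    r2_start=r2.reference_start,
                    r2_seq=r2.query_sequence,
                    r1_qual=r1.qual,
                    r2_qual=r2.qual,
                    sample=sample,
                    replicate=replicate,
                )
            )
    n_orphans = len(pending)
    if n_orphans:
        logger.warning("%s: %d orphan reads without a mate were skipped", path, n_orphans)
    return fragments, n_orphans
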