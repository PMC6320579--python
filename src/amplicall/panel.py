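"""Amplicon panel model: loading, validation, blacklisting.

Every downstream stage (read assignment, coverage, per-amplicon calling) is
keyed on the panel.  Internal coordinates are 0-based half-open everywhere;
conversion to 1-based happens only at the VCF boundary.

Panel files are TSV with header
``id gene chrom fwd_start fwd_end rev_start rev_end pool [fwd_seq rev_seq]``.
A leading directive line ``#coords=1-based-inclusive`` (or
``0-based-half-open``, the default) declares the coordinate dialect; inputs
are normalised on load so the in-memory representation is always the same.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

# Intended outer amplicon length range for short cfDNA fragments (bp).
# Violations are design warnings, not errors.
MIN_AMPLICON_LEN = 69
MAX_AMPLICON_LEN = 157

# Multiplex pools are designed to hold 7-8 primer pairs from distinct genes.
POOL_SIZES = (7, 8)

PANEL_COLUMNS = ["id", "gene", "chrom", "fwd_start", "fwd_end", "rev_start", "rev_end", "pool"]
OPTIONAL_COLUMNS = ["fwd_seq", "rev_seq"]


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel inputs."""


@dataclass(frozen=True)
class Amplicon:
    """One primer pair and the genomic region it amplifies.

    Coordinates are 0-based half-open.  The *outer* span runs from the start
    of the forward primer to the end of the reverse primer; the *insert* is
    the region between the primers, which is where variants are called.
    """

    id: str
    gene: str
    chrom: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    pool: int
    fwd_seq: str | None = None
    rev_seq: str | None = None

    def __post_init__(self) -> None:
        for lo, hi, what in (
            (self.fwd_start, self.fwd_end, "forward primer"),
            (self.rev_start, self.rev_end, "reverse primer"),
            (self.insert_start, self.insert_end, "insert"),
        ):
            if lo >= hi:
                raise PanelError(f"amplicon {self.id}: {what} interval [{lo}, {hi}) is empty or inverted")

    @property
    def insert_start(self) -> int:
        return self.fwd_end

    @property
    def insert_end(self) -> int:
        return self.rev_start

    @property
    def outer_start(self) -> int:
        return self.fwd_start

    @property
    def outer_end(self) -> int:
        return self.rev_end

    @property
    def outer_length(self) -> int:
        return self.rev_end - self.fwd_start

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start


@dataclass
class Panel:
    """An ordered amplicon collection plus blacklist and optional reference.

    ``reference`` maps chromosome name to sequence (plain string or any
    object supporting slicing, e.g. a pyfaidx record); it is required for
    simulation and for REF alleles, optional otherwise.
    """

    amplicons: list[Amplicon]
    blacklist: set[str] = field(default_factory=set)
    reference: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [a.id for a in self.amplicons]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelError(f"duplicate amplicon ids: {sorted(dupes)}")
        unknown = self.blacklist - set(ids)
        if unknown:
            raise PanelError(f"blacklisted ids not in panel: {sorted(unknown)}")
        self._by_id = {a.id: a for a in self.amplicons}

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        return self._by_id[amplicon_id]

    def __contains__(self, amplicon_id: str) -> bool:
        return amplicon_id in self._by_id

    @property
    def active(self) -> list[Amplicon]:
        """Amplicons not excluded by the blacklist, in panel order."""
        return [a for a in self.amplicons if a.id not in self.blacklist]

    def ref_base(self, chrom: str, pos: int) -> str:
        if self.reference is None:
            raise PanelError("panel has no reference sequences")
        return str(self.reference[chrom][pos : pos + 1]).upper()

    def ref_slice(self, chrom: str, start: int, end: int) -> str:
        if self.reference is None:
            raise PanelError("panel has no reference sequences")
        return str(self.reference[chrom][start:end]).upper()

    def amplicons_at(self, chrom: str, pos: int) -> list[Amplicon]:
        """Active amplicons whose insert covers ``pos``."""
        return [
            a
            for a in self.active
            if a.chrom == chrom and a.insert_start <= pos < a.insert_end
        ]


@dataclass(frozen=True)
class PanelIssue:
    """One validation finding: which amplicon (or pool), which rule, severity."""

    amplicon_id: str
    rule: str
    severity: str
    message: str


def _read_dialect(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#coords="):
        dialect = first.split("=", 1)[1]
        if dialect not in ("0-based-half-open", "1-based-inclusive"):
            raise PanelError(f"unknown coordinate dialect {dialect!r}")
        return dialect
    return "0-based-half-open"


def load_panel(
    path: str | Path,
    reference: Mapping[str, str] | None = None,
    blacklist: Iterable[str] = (),
) -> Panel:
    """Load a TSV panel file, normalising coordinates to 0-based half-open.

    Raises :class:`PanelError` on an empty file, a duplicate id, or a
    malformed interval (start >= end), naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise PanelError(f"panel file not found: {path}")
    dialect = _read_dialect(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if df.empty:
        raise PanelError(f"panel file {path} contains no amplicons")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"panel file {path} missing columns: {missing}")

    amplicons = []
    for row in df.itertuples(index=False):
        coords = {c: int(getattr(row, c)) for c in ("fwd_start", "fwd_end", "rev_start", "rev_end")}
        if dialect == "1-based-inclusive":
            # [start, end] 1-based  ->  [start-1, end) 0-based half-open
            coords["fwd_start"] -= 1
            coords["rev_start"] -= 1
        for lo, hi in (("fwd_start", "fwd_end"), ("rev_start", "rev_end")):
            if coords[lo] >= coords[hi]:
                raise PanelError(
                    f"panel row {row.id}: {lo}={coords[lo]} >= {hi}={coords[hi]} after normalisation"
                )
        amplicons.append(
            Amplicon(
                id=str(row.id),
                gene=str(row.gene),
                chrom=str(row.chrom),
                pool=int(row.pool),
                fwd_seq=str(row.fwd_seq) if "fwd_seq" in df.columns and pd.notna(row.fwd_seq) else None,
                rev_seq=str(row.rev_seq) if "rev_seq" in df.columns and pd.notna(row.rev_seq) else None,
                **coords,
            )
        )
    return Panel(amplicons=amplicons, blacklist=set(blacklist), reference=reference)


def load_panel_bed(
    path: str | Path,
    primer_len: int = 20,
    reference: Mapping[str, str] | None = None,
) -> Panel:
    """Import shim for BED6-style insert intervals.

    BED rows give insert coordinates (0-based half-open by the BED contract);
    primers of ``primer_len`` bp are synthesised flanking each insert.  The
    BED name column becomes the amplicon id; gene is the id up to the first
    underscore; score is reused as the pool index when integral, else pool 1.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    if df.empty:
        raise PanelError(f"BED file {path} contains no intervals")
    amplicons = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        try:
            pool = int(row.score)
        except (TypeError, ValueError):
            pool = 1
        amplicons.append(
            Amplicon(
                id=str(row.name),
                gene=str(row.name).split("_")[0],
                chrom=str(row.chrom),
                fwd_start=start - primer_len,
                fwd_end=start,
                rev_start=end,
                rev_end=end + primer_len,
                pool=pool,
            )
        )
    return Panel(amplicons=amplicons, reference=reference)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to the canonical TSV dialect (round-trip safe)."""
    rows = []
    for a in panel.amplicons:
        rows.append(
            {
                "id": a.id,
                "gene": a.gene,
                "chrom": a.chrom,
                "fwd_start": a.fwd_start,
                "fwd_end": a.fwd_end,
                "rev_start": a.rev_start,
                "rev_end": a.rev_end,
                "pool": a.pool,
                "fwd_seq": a.fwd_seq if a.fwd_seq else "",
                "rev_seq": a.rev_seq if a.rev_seq else "",
            }
        )
    with open(path, "w") as fh:
        fh.write("#coords=0-based-half-open\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def validate_panel(panel: Panel) -> list[PanelIssue]:
    """Report design-rule violations; an empty report means the panel conforms.

    Checks: outer amplicon length within 69-157 bp, pool sizes of 7-8, and
    no two amplicons of the same gene within one pool.  All findings are
    warnings — the panel remains usable.
    """
    issues: list[PanelIssue] = []
    for a in panel.amplicons:
        if not (MIN_AMPLICON_LEN <= a.outer_length <= MAX_AMPLICON_LEN):
            issues.append(
                PanelIssue(
                    a.id,
                    "amplicon_length",
                    "warning",
                    f"outer length {a.outer_length} bp outside {MIN_AMPLICON_LEN}-{MAX_AMPLICON_LEN} bp",
                )
            )
    pools: dict[int, list[Amplicon]] = {}
    for a in panel.amplicons:
        pools.setdefault(a.pool, []).append(a)
    for pool, members in sorted(pools.items()):
        if len(members) not in POOL_SIZES:
            issues.append(
                PanelIssue(
                    f"pool:{pool}",
                    "pool_size",
                    "warning",
                    f"pool {pool} has {len(members)} amplicons (expected 7-8)",
                )
            )
        genes = [m.gene for m in members]
        for gene in sorted({g for g in genes if genes.count(g) > 1}):
            issues.append(
                PanelIssue(
                    f"pool:{pool}",
                    "pool_gene_clash",
                    "warning",
                    f"pool {pool} contains multiple amplicons of gene {gene}",
                )
            )
    return issues


def apply_blacklist(panel: Panel, ids: Iterable[str]) -> Panel:
    """Mark amplicons as excluded from coverage and calling.

    Unknown ids raise; blacklisting every amplicon yields an empty active
    panel with a warning (not an error), so parameter sweeps do not crash.
    """
    ids = set(ids)
    unknown = ids - {a.id for a in panel.amplicons}
    if unknown:
        raise PanelError(f"cannot blacklist unknown amplicon ids: {sorted(unknown)}")
    new_blacklist = panel.blacklist | ids
    if len(new_blacklist) == len(panel.amplicons):
        warnings.warn("blacklist covers every amplicon: active panel is empty", stacklevel=2)
    return Panel(amplicons=list(panel.amplicons), blacklist=new_blacklist, reference=panel.reference)


def load_reference_fasta(path: str | Path) -> Mapping[str, str]:
    """Load a FASTA reference as a chrom -> sequence mapping via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: fa[name][:] for name in fa.keys()}
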