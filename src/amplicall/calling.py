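"""Per-amplicon tumour/normal mutation calling and the replicate-consensus cascade.

The cascade, applied per amplicon:

1. candidate detection in each plasma replicate against the matched normal
   (pileup thresholding: minimum alt reads and alt fraction);
2. pair filters: plasma and normal coverage > 100x, normal alt fraction < 1%,
   plasma/normal VAF ratio > 5 — failing candidates are *flagged*, not
   discarded, so external-caller rescues can reuse the same machinery;
3. replicate consensus: keep variants with passing candidates in >= 2 of 3
   replicates, re-genotyping the VAF in every replicate to form the average;
4. average filter: keep avg VAF >= 1% and average plasma/normal ratio >= 5;
5. optional FFPE filter: drop C>T / G>A transitions below 15% VAF, the
   signature of fixation-induced cytosine deamination.

An external per-amplicon VCF (e.g. from a haplotype-based somatic caller) can
be ingested instead of step 1; records failing only whitelisted caller-internal
filters are rescued and flow through the same pair filters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from amplicall.panel import Amplicon, Panel
from amplicall.reads import (
    DEFAULT_TRIM,
    AlignedFragment,
    BASES,
    FragmentBatch,
    N_CODE,
    encode_bases,
)

logger = logging.getLogger(__name__)

# Allele-class layout of pileup count matrices.
ALLELE_CLASSES = ("A", "C", "G", "T", "DEL", "INS")
N_CLASSES = len(ALLELE_CLASSES)

# Caller-internal filter names rescued when ingesting an external VCF.
DEFAULT_FILTER_WHITELIST = frozenset(
    {
        "alt_allele_in_normal",
        "clustered_events",
        "homologous_mapping_event",
        "multi_event_alt_allele_in_normal",
    }
)


@dataclass
class FilterConfig:
    """All thresholds of the calling cascade, defaulting to the published values."""

    min_depth: int = 100  # strict >, plasma and normal
    max_normal_vaf: float = 0.01  # strict <
    min_ratio: float = 5.0  # plasma/normal VAF, strict > at pair level
    min_replicates: int = 2
    min_avg_vaf: float = 0.01  # keep avg VAF >= 1%
    ffpe_min_vaf: float = 0.15  # C>T / G>A below this are deamination artefacts
    group_min_vaf: float = 0.05  # longitudinal group filter, strict >
    min_alt_reads: int = 3  # candidate emission, per replicate
    min_alt_fraction: float = 0.005
    # The published removal clause couples low average VAF and low average
    # ratio ambiguously; "and" keeps variants passing BOTH keep-conditions
    # (avg_vaf >= min_avg_vaf AND avg_ratio >= min_ratio), "or" keeps variants
    # passing either.
    avg_filter_mode: str = "and"

    def __post_init__(self) -> None:
        for name in ("max_normal_vaf", "min_avg_vaf", "ffpe_min_vaf", "group_min_vaf", "min_alt_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.avg_filter_mode not in ("and", "or"):
            raise ValueError("avg_filter_mode must be 'and' or 'or'")


@dataclass(frozen=True)
class PileupColumn:
    """Allele counts at one insert position of one amplicon."""

    chrom: str
    pos: int
    amplicon_id: str
    counts: tuple[int, ...]  # aligned with ALLELE_CLASSES

    @property
    def depth(self) -> int:
        return sum(self.counts)


@dataclass
class AmpliconPileup:
    """Dense pileup over one amplicon's insert: counts[pos, allele_class]."""

    amplicon_id: str
    chrom: str
    insert_start: int
    insert_end: int
    ref_codes: np.ndarray  # (L,)
    counts: np.ndarray  # (L, N_CLASSES) int64

    @property
    def length(self) -> int:
        return self.insert_end - self.insert_start

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def columns(self) -> Iterable[PileupColumn]:
        for i in range(self.length):
            yield PileupColumn(
                chrom=self.chrom,
                pos=self.insert_start + i,
                amplicon_id=self.amplicon_id,
                counts=tuple(int(c) for c in self.counts[i]),
            )

    def site_stats(self, pos: int, alt: str) -> tuple[int, float]:
        """(depth, alt fraction) at one genomic position for one alt base."""
        i = pos - self.insert_start
        if not (0 <= i < self.length):
            raise ValueError(f"position {pos} outside insert of {self.amplicon_id}")
        depth = int(self.counts[i].sum())
        if depth == 0:
            return 0, 0.0
        return depth, float(self.counts[i, BASES.index(alt)]) / depth


def pileup(
    fragments: FragmentBatch | Sequence[AlignedFragment],
    amplicon: Amplicon,
    panel: Panel,
    trim: int | None = DEFAULT_TRIM,
) -> AmpliconPileup:
    """Count base calls per insert position from the amplicon's fragments.

    Trimming at ``trim`` bp (5'-anchored per mate) is applied here so callers
    can hand over raw batches; pass ``trim=None`` for pre-trimmed input.
    Both mates contribute independently where their trimmed spans overlap.
    """
    ins_s, ins_e = amplicon.insert_start, amplicon.insert_end
    L = ins_e - ins_s
    ref_codes = encode_bases(panel.ref_slice(amplicon.chrom, ins_s, ins_e))
    counts = np.zeros((L, N_CLASSES), dtype=np.int64)

    if isinstance(fragments, FragmentBatch):
        batch = fragments.trimmed(trim) if trim is not None else fragments
        for mat, start in ((batch.r1, batch.start), (batch.r2, batch.r2_start)):
            if mat.size == 0:
                continue
            lo = max(ins_s, start)
            hi = min(ins_e, start + mat.shape[1])
            for pos in range(lo, hi):
                col = np.bincount(mat[:, pos - start], minlength=5)[:4]
                counts[pos - ins_s, :4] += col
    else:
        from amplicall.reads import trim_fragment

        for frag in fragments:
            f = trim_fragment(frag, trim) if trim is not None else frag
            for seq, start in ((f.r1_seq, f.r1_start), (f.r2_seq, f.r2_start)):
                codes = encode_bases(seq)
                lo = max(ins_s, start)
                hi = min(ins_e, start + len(codes))
                for pos in range(lo, hi):
                    c = codes[pos - start]
                    if c < 4:
                        counts[pos - ins_s, c] += 1
    return AmpliconPileup(
        amplicon_id=amplicon.id,
        chrom=amplicon.chrom,
        insert_start=ins_s,
        insert_end=ins_e,
        ref_codes=ref_codes,
        counts=counts,
    )


@dataclass
class CandidateVariant:
    """A per-replicate candidate call with its tumour/normal pair statistics."""

    chrom: str
    pos: int
    ref: str
    alt: str
    amplicon_id: str | None
    replicate: int
    plasma_depth: int
    plasma_vaf: float
    normal_depth: int
    normal_vaf: float
    flags: frozenset[str] = frozenset()

    @property
    def ratio(self) -> float:
        if self.normal_vaf == 0.0:
            return math.inf
        return self.plasma_vaf / self.normal_vaf

    @property
    def passed(self) -> bool:
        return not self.flags

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def pair_filter_flags(
    plasma_depth: int,
    plasma_vaf: float,
    normal_depth: int,
    normal_vaf: float,
    cfg: FilterConfig,
) -> frozenset[str]:
    """Tumour/normal pair filters shared by the internal caller and VCF ingestion."""
    flags = set()
    if not (plasma_depth > cfg.min_depth and normal_depth > cfg.min_depth):
        flags.add("low_coverage")
    if not (normal_vaf < cfg.max_normal_vaf):
        flags.add("normal_contaminated")
    ratio = math.inf if normal_vaf == 0.0 else plasma_vaf / normal_vaf
    if not (ratio > cfg.min_ratio):
        flags.add("low_ratio")
    return frozenset(flags)


def call_candidates(
    plasma: AmpliconPileup,
    normal: AmpliconPileup,
    cfg: FilterConfig,
    replicate: int = 0,
) -> list[CandidateVariant]:
    """Emit candidates for one plasma replicate against the matched normal.

    A candidate arises wherever a non-reference base reaches both
    ``min_alt_reads`` and ``min_alt_fraction`` in the plasma pileup; the pair
    filters then annotate (never remove) the candidate.  Substitutions only.
    """
    if plasma.amplicon_id != normal.amplicon_id:
        raise ValueError(
            f"plasma amplicon {plasma.amplicon_id} != normal amplicon {normal.amplicon_id}"
        )
    p_depth = plasma.depth
    n_depth = normal.depth
    out: list[CandidateVariant] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        p_frac = np.where(p_depth[:, None] > 0, plasma.counts[:, :4] / np.maximum(p_depth[:, None], 1), 0.0)
    for alt_code in range(4):
        mask = (
            (plasma.ref_codes != alt_code)
            & (plasma.counts[:, alt_code] >= cfg.min_alt_reads)
            & (p_frac[:, alt_code] >= cfg.min_alt_fraction)
        )
        for i in np.flatnonzero(mask):
            nd = int(n_depth[i])
            nvaf = float(normal.counts[i, alt_code]) / nd if nd > 0 else 0.0
            pd_ = int(p_depth[i])
            pvaf = float(p_frac[i, alt_code])
            out.append(
                CandidateVariant(
                    chrom=plasma.chrom,
                    pos=plasma.insert_start + int(i),
                    ref=BASES[int(plasma.ref_codes[i])],
                    alt=BASES[alt_code],
                    amplicon_id=plasma.amplicon_id,
                    replicate=replicate,
                    plasma_depth=pd_,
                    plasma_vaf=pvaf,
                    normal_depth=nd,
                    normal_vaf=nvaf,
                    flags=pair_filter_flags(pd_, pvaf, nd, nvaf, cfg),
                )
            )
    out.sort(key=lambda c: (c.pos, c.alt))
    return out


def ingest_external_vcf(
    path: str | Path,
    whitelist: frozenset[str] = DEFAULT_FILTER_WHITELIST,
    cfg: FilterConfig | None = None,
    tumor_sample: str | None = None,
    normal_sample: str | None = None,
    replicate: int = 0,
    panel: Panel | None = None,
) -> list[CandidateVariant]:
    """Ingest an external per-amplicon tumour/normal VCF as candidates.

    A record is retained iff its FILTER is PASS (or missing) or *every*
    failing filter is in the whitelist; unknown non-whitelisted tokens drop
    the record with a log line.  Retained records then pass through the same
    pair filters as the internal caller, using per-sample AF/AD and DP.
    Indels pass through untouched by the substitution-only internal caller.
    """
    import pysam

    cfg = cfg or FilterConfig()
    out: list[CandidateVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if not sample_names:
            raise ValueError(f"{path}: VCF has no sample columns")
        t_name = tumor_sample or sample_names[0]
        n_name = normal_sample or (sample_names[1] if len(sample_names) > 1 else None)
        for rec in vcf:
            filters = set(rec.filter.keys())
            if filters and filters != {"PASS"}:
                if not filters <= whitelist:
                    logger.info(
                        "%s:%d dropped, non-whitelisted filters %s",
                        rec.chrom,
                        rec.pos,
                        sorted(filters - whitelist),
                    )
                    continue
            for alt in rec.alts or ():
                t = rec.samples[t_name]
                pd_, pvaf = _sample_depth_vaf(t, rec, alt)
                if n_name is not None:
                    nd, nvaf = _sample_depth_vaf(rec.samples[n_name], rec, alt)
                else:
                    nd, nvaf = 0, 0.0
                amp_id = None
                if "AMP" in rec.info:
                    amp_id = str(rec.info["AMP"])
                elif panel is not None:
                    hits = panel.amplicons_at(rec.chrom, rec.pos - 1)
                    amp_id = hits[0].id if hits else None
                out.append(
                    CandidateVariant(
                        chrom=rec.chrom,
                        pos=rec.pos - 1,  # VCF is 1-based
                        ref=rec.ref,
                        alt=alt,
                        amplicon_id=amp_id,
                        replicate=replicate,
                        plasma_depth=pd_,
                        plasma_vaf=pvaf,
                        normal_depth=nd,
                        normal_vaf=nvaf,
                        flags=pair_filter_flags(pd_, pvaf, nd, nvaf, cfg),
                    )
                )
    return out


def _sample_depth_vaf(sample, rec, alt) -> tuple[int, float]:
    depth = int(sample.get("DP") or 0)
    af = sample.get("AF")
    if af is not None:
        alt_i = (rec.alts or ()).index(alt)
        vaf = float(af[alt_i] if isinstance(af, tuple) else af)
        return depth, vaf
    ad = sample.get("AD")
    if ad is not None:
        alt_i = (rec.alts or ()).index(alt)
        total = sum(int(x) for x in ad if x is not None)
        if depth == 0:
            depth = total
        return depth, (int(ad[alt_i + 1]) / total if total else 0.0)
    return depth, 0.0


@dataclass
class ConsensusVariant:
    """Cross-replicate aggregate of one candidate variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    amplicon_id: str | None
    replicates_called: int
    n_replicates: int
    per_replicate_vafs: tuple[float, ...]
    avg_vaf: float
    avg_depth: float
    normal_vaf: float
    status: frozenset[str] = frozenset()

    @property
    def avg_ratio(self) -> float:
        if self.normal_vaf == 0.0:
            return math.inf
        return self.avg_vaf / self.normal_vaf

    @property
    def passed(self) -> bool:
        return not self.status

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def consensus(
    candidates_by_replicate: Mapping[int, Sequence[CandidateVariant]],
    plasma_pileups: Mapping[int, Mapping[str, AmpliconPileup]],
    normal_pileups: Mapping[str, AmpliconPileup],
    cfg: FilterConfig,
) -> list[ConsensusVariant]:
    """Aggregate per-replicate candidates into consensus variants.

    Only variants with *passing* candidates in at least ``min_replicates``
    replicates are kept.  The average VAF is the mean plasma alt fraction
    re-genotyped from the pileup in **every** replicate, called or not, so a
    variant missed by the caller in one replicate still contributes its
    measured signal.
    """
    reps = sorted(plasma_pileups.keys())
    passing: dict[tuple, set[int]] = {}
    meta: dict[tuple, CandidateVariant] = {}
    for rep, cands in candidates_by_replicate.items():
        for c in cands:
            meta.setdefault(c.key, c)
            if c.passed:
                passing.setdefault(c.key, set()).add(rep)

    out: list[ConsensusVariant] = []
    for key, called_in in sorted(passing.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][3])):
        if len(called_in) < cfg.min_replicates:
            continue
        c0 = meta[key]
        chrom, pos, ref, alt = key
        amp_id = c0.amplicon_id
        vafs, depths = [], []
        for rep in reps:
            pu = plasma_pileups[rep].get(amp_id) if amp_id else None
            if pu is None:
                vafs.append(0.0)
                depths.append(0.0)
                continue
            d, v = pu.site_stats(pos, alt)
            vafs.append(v)
            depths.append(float(d))
        n_pu = normal_pileups.get(amp_id) if amp_id else None
        if n_pu is not None:
            _, nvaf = n_pu.site_stats(pos, alt)
        else:
            nvaf = c0.normal_vaf
        out.append(
            ConsensusVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                amplicon_id=amp_id,
                replicates_called=len(called_in),
                n_replicates=len(reps),
                per_replicate_vafs=tuple(vafs),
                avg_vaf=float(np.mean(vafs)) if vafs else 0.0,
                avg_depth=float(np.mean(depths)) if depths else 0.0,
                normal_vaf=nvaf,
            )
        )
    return out


def average_vaf_filter(variants: Sequence[ConsensusVariant], cfg: FilterConfig) -> list[ConsensusVariant]:
    """Keep variants whose average VAF and average plasma/normal ratio clear
    the post-consensus thresholds; failing variants are flagged and removed."""
    kept = []
    for v in variants:
        ok_vaf = v.avg_vaf >= cfg.min_avg_vaf
        ok_ratio = v.avg_ratio >= cfg.min_ratio
        ok = (ok_vaf and ok_ratio) if cfg.avg_filter_mode == "and" else (ok_vaf or ok_ratio)
        if ok:
            kept.append(v)
        else:
            flags = set(v.status)
            if not ok_vaf:
                flags.add("below_avg_vaf")
            if not ok_ratio:
                flags.add("low_avg_ratio")
            v.status = frozenset(flags)
    return kept


_FFPE_PAIRS = {("C", "T"), ("G", "A")}


def ffpe_filter(
    variants: Sequence[ConsensusVariant],
    sample_is_ffpe: bool,
    cfg: FilterConfig,
) -> list[ConsensusVariant]:
    """Remove low-VAF C>T / G>A transitions from fixed-tissue samples.

    Cytosine deamination during fixation produces these transitions at low
    allele fractions; variants at or above ``ffpe_min_vaf`` are kept.  For
    non-FFPE samples the filter is the identity.
    """
    if not sample_is_ffpe:
        return list(variants)
    kept = []
    for v in variants:
        if (v.ref, v.alt) in _FFPE_PAIRS and v.avg_vaf < cfg.ffpe_min_vaf:
            v.status = frozenset(set(v.status) | {"ffpe_filtered"})
        else:
            kept.append(v)
    return kept


def write_variant_vcf(
    variants: Sequence[ConsensusVariant],
    panel: Panel,
    path: str | Path,
    sample_name: str = "PLASMA",
) -> None:
    """Write final consensus variants as a single-sample VCF (1-based POS)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "amplicall-call")
    if panel.reference is not None:
        for chrom in panel.reference:
            header.contigs.add(chrom, length=len(panel.reference[chrom]))
    else:
        chrom_max: dict[str, int] = {}
        for a in panel.amplicons:
            chrom_max[a.chrom] = max(chrom_max.get(a.chrom, 0), a.outer_end + 1000)
        for chrom, ln in chrom_max.items():
            header.contigs.add(chrom, length=ln)
    header.info.add("AMP", 1, "String", "Amplicon of the call")
    header.info.add("NREP", 1, "Integer", "Replicates in which the variant was called")
    header.formats.add("DP", 1, "Integer", "Mean plasma depth across replicates")
    header.formats.add("AF", 1, "Float", "Mean plasma VAF across replicates")
    header.add_sample(sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.alt)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos, stop=v.pos + len(v.ref), alleles=(v.ref, v.alt)
            )
            rec.info["AMP"] = v.amplicon_id or "."
            rec.info["NREP"] = v.replicates_called
            rec.samples[sample_name]["DP"] = int(round(v.avg_depth))
            rec.samples[sample_name]["AF"] = float(v.avg_vaf)
            out.write(rec)


def variants_to_table(variants: Sequence[ConsensusVariant]):
    """Final variants as a tidy DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "amplicon": v.amplicon_id,
                "replicates_called": v.replicates_called,
                "avg_vaf": v.avg_vaf,
                "avg_depth": v.avg_depth,
                "normal_vaf": v.normal_vaf,
                "avg_ratio": v.avg_ratio,
                "status": ";".join(sorted(v.status)) or "PASS",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "amplicon",
            "replicates_called",
            "avg_vaf",
            "avg_depth",
            "normal_vaf",
            "avg_ratio",
            "status",
        ],
    )


@dataclass
class CallResult:
    """Everything produced by the cascade for one sample (replicate trio)."""

    candidates: dict[int, list[CandidateVariant]]
    consensus: list[ConsensusVariant]
    variants: list[ConsensusVariant]  # final, post average-VAF and FFPE filters
    plasma_pileups: dict[int, dict[str, AmpliconPileup]]
    normal_pileups: dict[str, AmpliconPileup]


def call_sample(
    plasma_replicates: Sequence[Mapping[str, FragmentBatch]],
    normal_batches: Mapping[str, FragmentBatch],
    panel: Panel,
    cfg: FilterConfig | None = None,
    is_ffpe: bool = False,
    trim: int | None = DEFAULT_TRIM,
) -> CallResult:
    """Run the full cascade for one sample: pileups -> candidates -> consensus
    -> average-VAF filter -> FFPE filter.

    ``plasma_replicates`` maps amplicon id to :class:`FragmentBatch` for each
    replicate; ``normal_batches`` likewise for the single matched normal.
    """
    cfg = cfg or FilterConfig()
    amps = {a.id: a for a in panel.active}
    normal_pu = {
        amp_id: pileup(batch, amps[amp_id], panel, trim)
        for amp_id, batch in normal_batches.items()
        if amp_id in amps
    }
    plasma_pu: dict[int, dict[str, AmpliconPileup]] = {}
    candidates: dict[int, list[CandidateVariant]] = {}
    for rep, batches in enumerate(plasma_replicates):
        plasma_pu[rep] = {
            amp_id: pileup(batch, amps[amp_id], panel, trim)
            for amp_id, batch in batches.items()
            if amp_id in amps
        }
        cands: list[CandidateVariant] = []
        for amp_id, pu in plasma_pu[rep].items():
            if amp_id in normal_pu:
                cands.extend(call_candidates(pu, normal_pu[amp_id], cfg, rep))
        candidates[rep] = cands
    cons = consensus(candidates, plasma_pu, normal_pu, cfg)
    final = average_vaf_filter(cons, cfg)
    final = ffpe_filter(final, is_ffpe, cfg)
    return CallResult(
        candidates=candidates,
        consensus=cons,
        variants=final,
        plasma_pileups=plasma_pu,
        normal_pileups=normal_pu,
    )
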