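"""Longitudinal patient-level workflow: union of calls, force genotyping,
group-level filter, merged multi-sample VCF.

Given a patient's matched normal (buffy coat) and an ordered set of plasma /
tissue timepoints (each a replicate trio), the workflow (i) runs the
single-sample cascade independently per timepoint, (ii) takes the union of
all surviving variants, (iii) re-measures depth and VAF of every variant in
every timepoint regardless of call status ("force genotyping"), (iv) keeps
only variants exceeding 5% VAF in at least one timepoint, and (v) merges
everything into one multi-sample VCF with per-timepoint DP/AF columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from amplicall.calling import (
    AmpliconPileup,
    CallResult,
    FilterConfig,
    call_sample,
)
from amplicall.panel import Panel, PanelError
from amplicall.reads import FragmentBatch


@dataclass
class SampleRecord:
    """One timepoint: replicate fragment sets plus metadata."""

    label: str
    replicates: Sequence[Mapping[str, FragmentBatch]]
    is_ffpe: bool = False
    day: int | None = None

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValueError(f"sample {self.label}: at least one replicate required")


@dataclass
class PatientSeries:
    """A patient's matched normal plus ordered timepoints on one panel."""

    patient_id: str
    normal: Mapping[str, FragmentBatch]
    samples: Sequence[SampleRecord]
    panel: Panel

    def __post_init__(self) -> None:
        labels = [s.label for s in self.samples]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate sample labels in series {self.patient_id}")


@dataclass
class TrackedVariant:
    """One variant measured across every timepoint of a series."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    amplicon_id: str
    per_sample: dict[str, dict]  # label -> {depth, vaf, called}
    group_pass: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def max_vaf(self) -> float:
        vafs = [s["vaf"] for s in self.per_sample.values() if s["vaf"] is not None]
        return max(vafs) if vafs else 0.0


def call_series(series: PatientSeries, cfg: FilterConfig | None = None) -> dict[str, CallResult]:
    """Run the single-sample cascade independently for every timepoint."""
    cfg = cfg or FilterConfig()
    return {
        s.label: call_sample(s.replicates, series.normal, series.panel, cfg, is_ffpe=s.is_ffpe)
        for s in series.samples
    }


def force_genotype(
    site: tuple[str, int, str, str],
    pileups_by_replicate: Mapping[int, Mapping[str, AmpliconPileup]],
    panel: Panel,
) -> tuple[float, float | None]:
    """Mean depth and mean alt fraction at a site across one sample's replicates.

    Returns ``(avg_depth, avg_vaf)``; when no replicate has coverage the VAF
    is ``None`` (missing), not zero.  When overlapping amplicons cover the
    site, the one with the higher mean depth is used.
    """
    chrom, pos, _ref, alt = site
    amps = panel.amplicons_at(chrom, pos)
    if not amps:
        raise PanelError(f"site {chrom}:{pos} is outside every active amplicon insert")
    best: tuple[float, float | None] | None = None
    for amp in amps:
        depths, vafs = [], []
        for rep in sorted(pileups_by_replicate):
            pu = pileups_by_replicate[rep].get(amp.id)
            if pu is None:
                continue
            d, v = pu.site_stats(pos, alt)
            depths.append(float(d))
            vafs.append(v if d > 0 else None)
        if not depths:
            continue
        avg_depth = float(np.mean(depths))
        measured = [v for v in vafs if v is not None]
        avg_vaf = float(np.mean(measured)) if measured else None
        if best is None or avg_depth > best[0]:
            best = (avg_depth, avg_vaf)
    return best if best is not None else (0.0, None)


def group_filter(tracked: Sequence[TrackedVariant], cfg: FilterConfig | None = None) -> list[TrackedVariant]:
    """Keep variants whose VAF exceeds the group threshold (strictly) in at
    least one timepoint; annotate ``group_pass`` on every record."""
    cfg = cfg or FilterConfig()
    kept = []
    for v in tracked:
        v.group_pass = v.max_vaf > cfg.group_min_vaf
        if v.group_pass:
            kept.append(v)
    return kept


def track_series(
    series: PatientSeries,
    cfg: FilterConfig | None = None,
) -> tuple[list[TrackedVariant], dict[str, CallResult]]:
    """Full longitudinal workflow up to (and including) the group filter.

    Returns the group-passing tracked variants (deduplicated across
    overlapping amplicons) and the per-timepoint call results.
    """
    cfg = cfg or FilterConfig()
    results = call_series(series, cfg)

    union: dict[tuple, str] = {}
    called_in: dict[tuple, set[str]] = {}
    for label, res in results.items():
        for v in res.variants:
            union.setdefault(v.key, v.amplicon_id)
            called_in.setdefault(v.key, set()).add(label)

    tracked: list[TrackedVariant] = []
    for key in sorted(union, key=lambda k: (k[0], k[1], k[3])):
        chrom, pos, ref, alt = key
        amps = series.panel.amplicons_at(chrom, pos)
        gene = amps[0].gene if amps else ""
        per_sample: dict[str, dict] = {}
        for s in series.samples:
            depth, vaf = force_genotype(key, results[s.label].plasma_pileups, series.panel)
            per_sample[s.label] = {
                "depth": depth,
                "vaf": vaf,
                "called": s.label in called_in.get(key, set()),
            }
        tracked.append(
            TrackedVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                amplicon_id=union[key] or (amps[0].id if amps else ""),
                per_sample=per_sample,
            )
        )
    return group_filter(tracked, cfg), results


def merge_and_annotate(
    tracked: Sequence[TrackedVariant],
    series: PatientSeries,
    vcf_path: str | Path,
) -> None:
    """Write the final variant set as a multi-sample VCF (one column per
    timepoint, DP/AF/CL FORMAT fields, gene annotation from the panel).

    Positions convert to 1-based at this boundary.  Contradictory reference
    alleles at one site (panel/reference inconsistency) raise.
    """
    import pysam

    by_site: dict[tuple[str, int], str] = {}
    for v in tracked:
        prev = by_site.setdefault((v.chrom, v.pos), v.ref)
        if prev != v.ref:
            raise PanelError(f"contradictory REF alleles at {v.chrom}:{v.pos}: {prev} vs {v.ref}")

    header = pysam.VariantHeader()
    header.add_meta("source", "amplicall-track")
    panel = series.panel
    if panel.reference is not None:
        for chrom in panel.reference:
            header.contigs.add(chrom, length=len(panel.reference[chrom]))
    else:
        chrom_max: dict[str, int] = {}
        for a in panel.amplicons:
            chrom_max[a.chrom] = max(chrom_max.get(a.chrom, 0), a.outer_end + 1000)
        for chrom, ln in chrom_max.items():
            header.contigs.add(chrom, length=ln)
    header.info.add("GENE", 1, "String", "Gene symbol from the amplicon panel")
    header.info.add("AMP", 1, "String", "Amplicon used for depth/VAF (highest mean depth)")
    header.formats.add("DP", 1, "Integer", "Mean read depth across replicates")
    header.formats.add("AF", 1, "Float", "Mean variant allele fraction across replicates")
    header.formats.add("CL", 1, "Integer", "1 if called by the per-sample cascade")
    labels = [s.label for s in series.samples]
    for label in labels:
        header.add_sample(label)

    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for v in sorted(tracked, key=lambda t: (t.chrom, t.pos, t.alt)):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos,
                stop=v.pos + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info["GENE"] = v.gene or "."
            rec.info["AMP"] = v.amplicon_id or "."
            for label in labels:
                cell = v.per_sample[label]
                rec.samples[label]["DP"] = int(round(cell["depth"]))
                rec.samples[label]["AF"] = float(cell["vaf"]) if cell["vaf"] is not None else None
                rec.samples[label]["CL"] = 1 if cell["called"] else 0
            out.write(rec)


def read_tracking_vcf(path: str | Path) -> list[TrackedVariant]:
    """Parse a multi-sample tracking VCF back into :class:`TrackedVariant`s."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        labels = list(vcf.header.samples)
        for rec in vcf:
            per_sample = {}
            for label in labels:
                s = rec.samples[label]
                af = s.get("AF")
                per_sample[label] = {
                    "depth": float(s.get("DP") or 0),
                    "vaf": float(af) if af is not None else None,
                    "called": bool(s.get("CL")),
                }
            out.append(
                TrackedVariant(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=str(rec.info.get("GENE", "")),
                    amplicon_id=str(rec.info.get("AMP", "")),
                    per_sample=per_sample,
                    group_pass=True,
                )
            )
    return out


def monitoring_table(tracked: Sequence[TrackedVariant], series: PatientSeries):
    """Long-format per-(variant, timepoint) table for monitoring plots."""
    import pandas as pd

    rows = []
    days = {s.label: s.day for s in series.samples}
    for v in tracked:
        for label, cell in v.per_sample.items():
            rows.append(
                {
                    "patient": series.patient_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": v.gene,
                    "sample": label,
                    "day": days.get(label),
                    "depth": cell["depth"],
                    "vaf": cell["vaf"],
                    "called": cell["called"],
                }
            )
    return pd.DataFrame(rows)
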