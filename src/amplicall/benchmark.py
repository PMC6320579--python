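"""Evaluation machinery: background-noise profiling, expected-vs-observed VAF
regression, sensitivity / false-positive analysis, and the germline-pair FP
protocol.

These mirror how amplicon ctDNA assays are validated on a two-genome dilution
series: per-position background noise should stay below ~0.3% for 99% of
targeted positions; observed VAF should regress linearly on expected VAF with
slope ~1; all truth sites should be recovered at >= 5% expected VAF with no
false positives above 3%; and swapping two germline-identical samples through
the tumour/normal cascade should yield no calls above 5% VAF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from amplicall.calling import (
    AmpliconPileup,
    CallResult,
    ConsensusVariant,
    FilterConfig,
    call_sample,
)
from amplicall.panel import Panel
from amplicall.reads import FragmentBatch
from amplicall.sim import (
    DilutionSeries,
    DilutionSpec,
    SimConfig,
    SimulatedSample,
    VariantSite,
    simulate_dilution_series,
)


@dataclass
class NoiseProfile:
    """Per-position mean non-reference base fraction across replicates."""

    table: pd.DataFrame  # columns: chrom, pos, mean_nonref, n_obs

    def quantile(self, q: float) -> float:
        return float(self.table["mean_nonref"].quantile(q))

    def fraction_at_or_below(self, threshold: float) -> float:
        return float((self.table["mean_nonref"] <= threshold).mean())

    @property
    def n_positions(self) -> int:
        return int(len(self.table))


def estimate_noise(
    pileup_sets: Sequence[Mapping[str, AmpliconPileup]],
    panel: Panel,
    exclude_sites: Sequence[tuple[str, int]] = (),
) -> NoiseProfile:
    """Background noise from truth-negative positions.

    ``pileup_sets`` is one pileup dict (amplicon id -> pileup) per
    sample-replicate.  For every targeted insert position not in
    ``exclude_sites``, the non-reference read fraction is averaged across the
    replicates where the position has non-zero depth; zero-depth positions
    are missing and excluded.
    """
    excluded = set(exclude_sites)
    acc: dict[tuple[str, int], list[float]] = {}
    for pus in pileup_sets:
        for amp_id, pu in pus.items():
            depth = pu.depth
            ref_counts = pu.counts[np.arange(pu.length), pu.ref_codes]
            with np.errstate(divide="ignore", invalid="ignore"):
                nonref = np.where(depth > 0, 1.0 - ref_counts / np.maximum(depth, 1), np.nan)
            for i in range(pu.length):
                key = (pu.chrom, pu.insert_start + i)
                if key in excluded or depth[i] == 0:
                    continue
                acc.setdefault(key, []).append(float(nonref[i]))
    rows = [
        {"chrom": c, "pos": p, "mean_nonref": float(np.mean(v)), "n_obs": len(v)}
        for (c, p), v in sorted(acc.items())
    ]
    return NoiseProfile(table=pd.DataFrame(rows))


@dataclass
class RegressionResult:
    """Observed-on-expected VAF linear fit."""

    slope: float
    ci_low: float
    ci_high: float
    r_squared: float
    intercept: float | None
    n: int
    points: pd.DataFrame  # expected, observed, plus identifying columns


def vaf_regression(points: pd.DataFrame, with_intercept: bool = True) -> RegressionResult:
    """Least-squares fit of observed on expected VAF, pooling all points.

    ``points`` must carry ``expected`` and ``observed`` columns; rows with a
    missing observation are dropped.  The slope's 95% confidence interval and
    the R-squared come from an ordinary least-squares fit (with an intercept
    by default; a through-the-origin option is provided).
    """
    import statsmodels.api as sm

    df = points.dropna(subset=["expected", "observed"])
    if df["expected"].nunique() < 2:
        raise ValueError("regression needs at least two distinct expected VAF values")
    x = df["expected"].to_numpy(float)
    y = df["observed"].to_numpy(float)
    X = sm.add_constant(x) if with_intercept else x[:, None]
    fit = sm.OLS(y, X).fit()
    slope_idx = 1 if with_intercept else 0
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[slope_idx]),
        ci_low=float(ci[slope_idx][0]),
        ci_high=float(ci[slope_idx][1]),
        r_squared=float(fit.rsquared),
        intercept=float(fit.params[0]) if with_intercept else None,
        n=int(len(df)),
        points=df.reset_index(drop=True),
    )


@dataclass
class SensitivityReport:
    """Per-dilution-point truth recovery plus the false-positive list."""

    per_point: pd.DataFrame  # fraction, expected_vaf, n_truth, n_detected
    false_positives: pd.DataFrame  # fraction, chrom, pos, ref, alt, avg_vaf
    fp_vaf_thresholds: tuple[float, float] = (0.03, 0.05)

    @property
    def max_fp_vaf(self) -> float:
        return float(self.false_positives["avg_vaf"].max()) if len(self.false_positives) else 0.0

    def n_fp_above(self, threshold: float) -> int:
        return int((self.false_positives["avg_vaf"] > threshold).sum())

    def summary(self) -> dict:
        lo, hi = self.fp_vaf_thresholds
        return {
            "max_fp_vaf": self.max_fp_vaf,
            f"n_fp_above_{lo:g}": self.n_fp_above(lo),
            f"n_fp_above_{hi:g}": self.n_fp_above(hi),
            "n_fp_total": int(len(self.false_positives)),
        }


def sensitivity_fp_report(
    calls_by_point: Mapping[float, Sequence[ConsensusVariant]],
    sites: Sequence[VariantSite],
    fp_vaf_thresholds: tuple[float, float] = (0.03, 0.05),
) -> SensitivityReport:
    """Compare final calls per dilution point against the truth sites.

    A false positive is any surviving call at a (position, allele) not in the
    truth set; its average VAF is reported so FP severity can be summarised
    at the 3% and 5% thresholds.
    """
    truth_keys = {s.key for s in sites}
    point_rows, fp_rows = [], []
    for fraction in sorted(calls_by_point, reverse=True):
        calls = calls_by_point[fraction]
        detected = {c.key for c in calls} & truth_keys
        point_rows.append(
            {
                "fraction": fraction,
                "expected_vaf": fraction / 2.0,
                "n_truth": len(truth_keys),
                "n_detected": len(detected),
            }
        )
        for c in calls:
            if c.key not in truth_keys:
                fp_rows.append(
                    {
                        "fraction": fraction,
                        "chrom": c.chrom,
                        "pos": c.pos,
                        "ref": c.ref,
                        "alt": c.alt,
                        "avg_vaf": c.avg_vaf,
                    }
                )
    return SensitivityReport(
        per_point=pd.DataFrame(point_rows),
        false_positives=pd.DataFrame(fp_rows, columns=["fraction", "chrom", "pos", "ref", "alt", "avg_vaf"]),
        fp_vaf_thresholds=fp_vaf_thresholds,
    )


def buffy_pair_fp(
    sample_a: Sequence[Mapping[str, FragmentBatch]],
    sample_b: Sequence[Mapping[str, FragmentBatch]],
    panel: Panel,
    cfg: FilterConfig | None = None,
) -> dict:
    """False-positive protocol on two germline-identical samples.

    Runs the full cascade with A's replicates as "tumour" against B's first
    replicate as normal, then vice versa.  Every call in either direction is
    by construction a false positive.  Returns both call lists and the count
    of FPs above 5% VAF.
    """
    cfg = cfg or FilterConfig()
    res_ab = call_sample(sample_a, sample_b[0], panel, cfg)
    res_ba = call_sample(sample_b, sample_a[0], panel, cfg)
    all_fps = list(res_ab.variants) + list(res_ba.variants)
    return {
        "a_vs_b": res_ab.variants,
        "b_vs_a": res_ba.variants,
        "n_fp": len(all_fps),
        "n_fp_above_5pct": sum(1 for v in all_fps if v.avg_vaf > 0.05),
        "max_fp_vaf": max((v.avg_vaf for v in all_fps), default=0.0),
    }


@dataclass
class BenchmarkReport:
    """End-to-end dilution-series benchmark: calls, regression, noise, FPs."""

    input_mass_ng: float
    regression: RegressionResult
    sensitivity: SensitivityReport
    noise: NoiseProfile
    calls_by_point: dict[float, list[ConsensusVariant]]

    def to_dict(self) -> dict:
        return {
            "input_mass_ng": self.input_mass_ng,
            "regression": {
                "slope": self.regression.slope,
                "ci_low": self.regression.ci_low,
                "ci_high": self.regression.ci_high,
                "r_squared": self.regression.r_squared,
                "n": self.regression.n,
            },
            "sensitivity": self.sensitivity.per_point.to_dict(orient="records"),
            "fp_summary": self.sensitivity.summary(),
            "noise": {
                "n_positions": self.noise.n_positions,
                "fraction_at_or_below_0.003": self.noise.fraction_at_or_below(0.003),
                "p99": self.noise.quantile(0.99),
            },
        }


def run_dilution_benchmark(
    panel: Panel,
    sites: Sequence[VariantSite],
    spec: DilutionSpec | None = None,
    sim_config: SimConfig | None = None,
    filter_config: FilterConfig | None = None,
    seed: int | None = 0,
    series: DilutionSeries | None = None,
) -> BenchmarkReport:
    """Simulate a dilution series (or reuse one) and evaluate the pipeline.

    Per dilution point the replicate trio is called against the matched
    normal; observed VAFs for the regression are re-genotyped per replicate
    from the plasma pileups at every truth site (so points below the calling
    threshold still contribute); the noise profile pools every truth-negative
    position over all plasma pileups.
    """
    spec = spec or DilutionSpec(sites=tuple(sites))
    sim_config = sim_config or SimConfig()
    filter_config = filter_config or FilterConfig()
    if series is None:
        series = simulate_dilution_series(panel, spec, sim_config, rng=seed)

    site_positions = [(s.chrom, s.pos) for s in sites]
    calls_by_point: dict[float, list[ConsensusVariant]] = {}
    reg_rows = []
    all_plasma_pileups: list[Mapping[str, AmpliconPileup]] = []
    for point in series.points:
        reps = [r.batches for r in point.replicates]
        res = call_sample(reps, series.normal.batches, panel, filter_config)
        calls_by_point[point.fraction] = res.variants
        for rep_idx, pus in res.plasma_pileups.items():
            all_plasma_pileups.append(pus)
            for site in sites:
                amps = panel.amplicons_at(site.chrom, site.pos)
                obs = None
                best_depth = -1
                for amp in amps:
                    pu = pus.get(amp.id)
                    if pu is None:
                        continue
                    d, v = pu.site_stats(site.pos, site.alt)
                    if d > best_depth:
                        best_depth, obs = d, (v if d > 0 else None)
                reg_rows.append(
                    {
                        "fraction": point.fraction,
                        "replicate": rep_idx,
                        "chrom": site.chrom,
                        "pos": site.pos,
                        "expected": point.expected_vaf,
                        "observed": obs,
                    }
                )
    regression = vaf_regression(pd.DataFrame(reg_rows))
    sensitivity = sensitivity_fp_report(calls_by_point, sites)
    noise = estimate_noise(all_plasma_pileups, panel, exclude_sites=site_positions)
    return BenchmarkReport(
        input_mass_ng=spec.input_mass_ng,
        regression=regression,
        sensitivity=sensitivity,
        noise=noise,
        calls_by_point=calls_by_point,
    )
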