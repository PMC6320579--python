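"""Virtual tumour/normal dilution-series simulator.

The benchmark this emulates mixes cell-free DNA of a deeply characterised
"tumour" genome into a matched "normal" genome by volume, across twelve
dilution points, so that a handful of heterozygous SNPs private to the tumour
line act as ground-truth somatic variants with expected VAF = fraction / 2
(from 50% down to 0.1%).  Template-copy numbers follow the DNA input mass
(~303 haploid copies per ng at 3.3 pg per haploid genome), which is what
makes low-input runs behave stochastically.

The error model is substitution-only: a per-base sequencing error rate plus
an effective PCR error (per-cycle rate x cycle count) applied at read level;
optional template-level "jackpot" errors (early-cycle PCR errors inherited by
many reads) can be switched on to produce VAF-correlated false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from amplicall.panel import Amplicon, Panel, PanelError
from amplicall.reads import BASES, FragmentBatch, decode_bases, encode_bases, revcomp

# Haploid genome copies per ng of human DNA (3.3 pg per haploid genome).
COPIES_PER_NG = 303.0

# Default volume fractions of the tumour line across the 12-point dilution
# series, spanning expected VAF 50% -> 0.1%.
DEFAULT_FRACTIONS = (1.0, 0.66, 0.50, 0.25, 0.10, 0.06, 0.04, 0.02, 0.01, 0.006, 0.004, 0.002)


@dataclass(frozen=True)
class VariantSite:
    """A single-base truth site, heterozygous in the tumour line.

    ``present_in_normal=False`` marks the site as a virtual somatic variant:
    absent from the normal line, so its expected VAF in a mixture is
    ``fraction / 2``.
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    present_in_normal: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class DilutionSpec:
    """Design of a dilution series: which fractions, sites, mass, replicates."""

    fractions: Sequence[float] = DEFAULT_FRACTIONS
    sites: Sequence[VariantSite] = ()
    input_mass_ng: float = 10.0
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(not (0.0 <= f <= 1.0) for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")
        self.fractions = tuple(sorted(self.fractions, reverse=True))


@dataclass
class SimConfig:
    """Tunable parameters of the read simulator.

    ``seq_error_rate`` is the per-base substitution probability at read level
    (default 1e-3, i.e. ~Q30 calls); ``pcr_error_per_cycle`` the per-base
    per-cycle polymerase substitution rate (default 3e-6, a high-fidelity
    enzyme), applied as an effective probability ``pcr_cycles x rate`` on the
    amplified molecule so both mates inherit the same PCR error.
    ``amplicon_efficiency_sd`` is the log-normal spread of per-amplicon yield.
    ``jackpot_rate`` (default off) is the per-amplicon probability of an
    early-cycle PCR error propagating to a visible template fraction.
    """

    copies_per_ng: float = COPIES_PER_NG
    target_depth: int = 3000
    read_len: int = 150
    seq_error_rate: float = 1e-3
    pcr_cycles: int = 30
    pcr_error_per_cycle: float = 3e-6
    amplicon_efficiency_sd: float = 0.15
    jackpot_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("seq_error_rate", "pcr_error_per_cycle", "jackpot_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.copies_per_ng <= 0:
            raise ValueError("copies_per_ng must be positive")

    @property
    def effective_pcr_error(self) -> float:
        return self.pcr_cycles * self.pcr_error_per_cycle


def genome_copies(mass_ng: float, copies_per_ng: float = COPIES_PER_NG) -> int:
    """Haploid genome copies contained in ``mass_ng`` ng of DNA."""
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    return int(round(mass_ng * copies_per_ng))


def expected_vaf(fraction: float) -> float:
    """Expected VAF of a tumour-line heterozygous site at a volume fraction."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    return fraction / 2.0


def draw_site_templates(copies: int, vaf: float, rng: np.random.Generator) -> int:
    """Number of input templates carrying the alternative allele.

    Binomial subsampling of ``copies`` amplifiable templates at the expected
    allele fraction; the rest carry the reference allele.  This is the stage
    that makes low-copy inputs noisy.
    """
    if copies < 0:
        raise ValueError("copies must be non-negative")
    return int(rng.binomial(copies, vaf)) if copies > 0 else 0


@dataclass
class SimulatedSample:
    """One simulated sample-replicate: per-amplicon read batches plus truth."""

    sample_id: str
    replicate: int
    role: str  # plasma | normal | buffy
    fraction: float
    batches: dict[str, FragmentBatch]
    truth: dict[tuple[str, int, str, str], float]  # site key -> realised template VAF
    template_counts: dict[str, int]


def _inject_substitutions(mat: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Apply uniform substitution errors in place to a base-code matrix."""
    if rate <= 0.0 or mat.size == 0:
        return
    n_err = rng.binomial(mat.size, rate)
    if n_err == 0:
        return
    idx = rng.integers(0, mat.size, size=n_err)
    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
    flat = mat.reshape(-1)
    flat[idx] = (flat[idx] + shift) % 4


def simulate_sample(
    panel: Panel,
    sites: Sequence[VariantSite],
    fraction: float,
    config: SimConfig,
    role: str = "plasma",
    rng: np.random.Generator | int | None = None,
    sample_id: str = "sample",
    replicate: int = 0,
    input_mass_ng: float = 10.0,
) -> SimulatedSample:
    """Simulate one sample-replicate over every active amplicon.

    Somatic truth sites receive alternative alleles only in ``plasma`` role
    (germline sites, ``present_in_normal=True``, are heterozygous in every
    role).  Alleles are injected at template level — a binomial draw of alt
    templates among the amplifiable copies — then reads resample templates,
    so realised VAFs carry both layers of sampling noise.
    """
    if panel.reference is None:
        raise PanelError("simulation requires a panel with reference sequences")
    if role not in ("plasma", "normal", "buffy"):
        raise ValueError(f"unknown sample role {role!r}")
    rng = np.random.default_rng(rng)
    sd = config.amplicon_efficiency_sd
    copies = genome_copies(input_mass_ng, config.copies_per_ng)
    batches: dict[str, FragmentBatch] = {}
    truth: dict[tuple[str, int, str, str], float] = {}
    template_counts: dict[str, int] = {}

    for amp in panel.active:
        L = amp.outer_length
        refseq = panel.ref_slice(amp.chrom, amp.outer_start, amp.outer_end)
        ref_codes = encode_bases(refseq)
        eff = float(np.exp(rng.normal(-0.5 * sd * sd, sd))) if sd > 0 else 1.0
        templates = int(rng.poisson(copies * eff))
        template_counts[amp.id] = templates
        n_reads = int(rng.poisson(config.target_depth * eff)) if templates > 0 else 0

        l1 = min(config.read_len, L)
        l2 = min(config.read_len, L)
        if n_reads == 0:
            batches[amp.id] = FragmentBatch(
                amplicon_id=amp.id,
                chrom=amp.chrom,
                start=amp.outer_start,
                end=amp.outer_end,
                r1=np.zeros((0, l1), dtype=np.uint8),
                r2=np.zeros((0, l2), dtype=np.uint8),
                sample=sample_id,
                replicate=replicate,
            )
            for site in sites:
                if site.chrom == amp.chrom and amp.insert_start <= site.pos < amp.insert_end:
                    truth[site.key] = float("nan")
            continue

        molecule = np.tile(ref_codes, (n_reads, 1))

        for site in sites:
            if site.chrom != amp.chrom or not (amp.insert_start <= site.pos < amp.insert_end):
                continue
            if site.present_in_normal:
                p_template = 0.5
            elif role == "plasma":
                p_template = expected_vaf(fraction)
            else:
                p_template = 0.0
            k = draw_site_templates(templates, p_template, rng)
            realised = k / templates if templates > 0 else 0.0
            truth[site.key] = realised
            n_alt = int(rng.binomial(n_reads, realised)) if realised > 0 else 0
            if n_alt > 0:
                rows = rng.permutation(n_reads)[:n_alt]
                molecule[rows, site.pos - amp.outer_start] = BASES.index(site.alt)

        if config.jackpot_rate > 0 and rng.random() < config.jackpot_rate:
            # Early-cycle PCR error: one random insert position gains a small
            # template fraction of a random alternative allele.
            off = int(rng.integers(amp.insert_start, amp.insert_end)) - amp.outer_start
            alt_code = (int(ref_codes[off]) + int(rng.integers(1, 4))) % 4
            jack_frac = min(1.0, float(2 ** rng.integers(1, 4)) / max(templates, 1))
            n_jack = int(rng.binomial(n_reads, jack_frac))
            if n_jack > 0:
                rows = rng.permutation(n_reads)[:n_jack]
                molecule[rows, off] = alt_code

        _inject_substitutions(molecule, config.effective_pcr_error, rng)

        r1 = molecule[:, :l1].copy()
        r2 = molecule[:, L - l2 :].copy()
        _inject_substitutions(r1, config.seq_error_rate, rng)
        _inject_substitutions(r2, config.seq_error_rate, rng)

        batches[amp.id] = FragmentBatch(
            amplicon_id=amp.id,
            chrom=amp.chrom,
            start=amp.outer_start,
            end=amp.outer_end,
            r1=r1,
            r2=r2,
            sample=sample_id,
            replicate=replicate,
        )

    return SimulatedSample(
        sample_id=sample_id,
        replicate=replicate,
        role=role,
        fraction=fraction if role == "plasma" else 0.0,
        batches=batches,
        truth=truth,
        template_counts=template_counts,
    )


@dataclass
class DilutionPoint:
    fraction: float
    expected_vaf: float
    replicates: list[SimulatedSample]


@dataclass
class DilutionSeries:
    """A full simulated dilution series plus its matched normal and truth."""

    points: list[DilutionPoint]
    normal: SimulatedSample
    sites: list[VariantSite]
    spec: DilutionSpec

    def truth_table(self) -> pd.DataFrame:
        """Expected and realised template VAF per (dilution point, site)."""
        rows = []
        for ip, point in enumerate(self.points):
            for site in self.sites:
                row = {
                    "point": ip,
                    "fraction": point.fraction,
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "ref": site.ref,
                    "alt": site.alt,
                    "expected_vaf": point.expected_vaf,
                }
                for rep in point.replicates:
                    row[f"template_vaf_rep{rep.replicate}"] = rep.truth.get(site.key, float("nan"))
                rows.append(row)
        return pd.DataFrame(rows)


def simulate_dilution_series(
    panel: Panel,
    spec: DilutionSpec,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> DilutionSeries:
    """Simulate every (dilution point x replicate) plus one matched normal."""
    rng = np.random.default_rng(rng)
    points = []
    for ip, fraction in enumerate(spec.fractions):
        reps = [
            simulate_sample(
                panel,
                spec.sites,
                fraction,
                config,
                role="plasma",
                rng=rng,
                sample_id=f"dil{ip:02d}",
                replicate=r,
                input_mass_ng=spec.input_mass_ng,
            )
            for r in range(spec.replicates)
        ]
        points.append(DilutionPoint(fraction=fraction, expected_vaf=expected_vaf(fraction), replicates=reps))
    normal = simulate_sample(
        panel,
        spec.sites,
        0.0,
        config,
        role="normal",
        rng=rng,
        sample_id="normal",
        replicate=0,
        input_mass_ng=spec.input_mass_ng,
    )
    return DilutionSeries(points=points, normal=normal, sites=list(spec.sites), spec=spec)


# ---------------------------------------------------------------------------
# Synthetic panel construction


def build_synthetic_panel(
    n_amplicons: int = 24,
    per_pool: int = 8,
    n_sites: int = 4,
    seed: int = 0,
    chrom: str = "sim1",
    primer_len: int = 20,
    spacing: int = 60,
) -> tuple[Panel, list[VariantSite]]:
    """Build a conforming toy panel on a random reference chromosome.

    Amplicons have outer lengths drawn in 90-157 bp (20 bp primers, 50-117 bp
    inserts), grouped into pools of ``per_pool`` amplicons from distinct
    genes.  The first ``n_sites`` amplicons each carry one heterozygous truth
    site at the middle of their insert, mirroring a benchmark in which four
    SNPs private to the tumour line are identifiable somatic variants.
    """
    rng = np.random.default_rng(seed)
    amplicons: list[Amplicon] = []
    sites: list[VariantSite] = []
    seq_parts: list[str] = []
    cursor = 0
    for i in range(n_amplicons):
        pad = "".join(BASES[c] for c in rng.integers(0, 4, size=spacing))
        seq_parts.append(pad)
        cursor += spacing
        outer_len = int(rng.integers(90, 158))
        amp_seq = "".join(BASES[c] for c in rng.integers(0, 4, size=outer_len))
        seq_parts.append(amp_seq)
        gene = f"GENE{i % per_pool + 1:02d}"
        amp = Amplicon(
            id=f"{gene}_{i:04d}_001",
            gene=gene,
            chrom=chrom,
            fwd_start=cursor,
            fwd_end=cursor + primer_len,
            rev_start=cursor + outer_len - primer_len,
            rev_end=cursor + outer_len,
            pool=i // per_pool + 1,
            fwd_seq=amp_seq[:primer_len],
            rev_seq=revcomp(amp_seq[-primer_len:]),
        )
        amplicons.append(amp)
        if i < n_sites:
            pos = (amp.insert_start + amp.insert_end) // 2
            ref = amp_seq[pos - cursor]
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            sites.append(VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt))
        cursor += outer_len
    seq_parts.append("".join(BASES[c] for c in rng.integers(0, 4, size=spacing)))
    reference = {chrom: "".join(seq_parts)}
    return Panel(amplicons=amplicons, reference=reference), sites


# ---------------------------------------------------------------------------
# Export of simulated reads


def _sam_header(panel: Panel) -> dict:
    if panel.reference is not None:
        chroms = {c: len(panel.reference[c]) for c in panel.reference}
    else:
        chroms = {}
        for a in panel.amplicons:
            chroms[a.chrom] = max(chroms.get(a.chrom, 0), a.outer_end + 1000)
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(ln)} for c, ln in chroms.items()],
    }


def write_sample_sam(sample: SimulatedSample, panel: Panel, path: str | Path) -> None:
    """Write a simulated sample as plain-text SAM (proper read pairs).

    Read names are deterministic (``sample:replicate:amplicon:index``) so the
    generating amplicon is recoverable as truth during pipeline tests.
    """
    import pysam

    header = pysam.AlignmentHeader.from_dict(_sam_header(panel))
    tid = {sq["SN"]: i for i, sq in enumerate(header.to_dict()["SQ"])}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for amp_id in sorted(sample.batches):
            batch = sample.batches[amp_id]
            for i in range(batch.n):
                name = f"{sample.sample_id}:{sample.replicate}:{amp_id}:{i}"
                for which, (seq_codes, start, flag) in enumerate(
                    [
                        (batch.r1[i], batch.start, 0x1 | 0x2 | 0x20 | 0x40),
                        (batch.r2[i], batch.r2_start, 0x1 | 0x2 | 0x10 | 0x80),
                    ]
                ):
                    a = pysam.AlignedSegment(header)
                    a.query_name = name
                    a.reference_id = tid[batch.chrom]
                    a.reference_start = start
                    a.mapping_quality = 60
                    a.cigarstring = f"{len(seq_codes)}M"
                    a.flag = flag
                    a.query_sequence = decode_bases(seq_codes)
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq_codes))
                    a.next_reference_id = tid[batch.chrom]
                    a.next_reference_start = batch.r2_start if which == 0 else batch.start
                    a.template_length = batch.length if which == 0 else -batch.length
                    out.write(a)


def write_sample_fastq(
    sample: SimulatedSample, path_r1: str | Path, path_r2: str | Path
) -> None:
    """Write a simulated sample as paired FASTQ.

    Mate 2 is emitted in sequencing orientation (reverse complement of its
    genomic-orientation storage).
    """
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for amp_id in sorted(sample.batches):
            batch = sample.batches[amp_id]
            for i in range(batch.n):
                name = f"{sample.sample_id}:{sample.replicate}:{amp_id}:{i}"
                s1 = decode_bases(batch.r1[i])
                s2 = revcomp(decode_bases(batch.r2[i]))
                f1.write(f"@{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
                f2.write(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")


def write_truth_table(series: DilutionSeries, path: str | Path) -> None:
    series.truth_table().to_csv(path, sep="\t", index=False)
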