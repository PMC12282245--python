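"""Synthetic electropherogram generator with truth labels.

Simulated peak heights follow the assay's signal model: the apex height of
each amplicon is proportional to its template copy number, scaled by a
per-target amplification efficiency, a shared per-sample amplification factor
and multiplicative (lognormal) noise.  Heights are positive and PCR
amplification acts multiplicatively, so lognormal noise is the natural model;
the default per-peak coefficient of variation (0.07) is on the scale of the
empirical spread of the validated ratio classes.

The generator produces peak tables directly, and optionally full raw traces
(Gaussian peaks on a constant baseline, plus the in-lane size ladder) so the
detection and calibration stages can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import (
    Genotype,
    PanelDefinition,
    class_signature,
    expected_copy_numbers,
)
from .peakio import Peak, PeakTable, SampleTrace

__all__ = [
    "SimulationParams",
    "SimulatedSample",
    "simulate_peak_table",
    "simulate_trace",
    "simulate_cohort",
    "table1_efficiency",
    "zero_noise_params",
]


@dataclass(frozen=True)
class SimulationParams:
    """Tunable generator parameters.

    noise_cv
        Sigma of the lognormal per-peak height noise (~ coefficient of
        variation for small values).
    scale_cv
        Sigma of the lognormal shared per-sample amplification factor;
        cancels in ratios, exercises scale invariance of calling.
    efficiency
        Per-target multiplicative amplification efficiency (default 1.0).
    """

    base_height: float = 2000.0          # RFU per template copy
    efficiency: dict = field(default_factory=dict)
    noise_cv: float = 0.07
    scale_cv: float = 0.0
    size_jitter_sd: float = 0.15         # bp
    dropout_height: float = 50.0         # RFU; smaller peaks are not reported
    # trace rendering
    sigma_peak: float = 8.0              # scans
    scan_offset: float = 500.0           # scan position of 0 bp
    scans_per_bp: float = 15.0
    scan_count: int = 10000
    baseline_level: float = 40.0         # RFU
    ladder_height: float = 600.0         # RFU

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.base_height <= 0:
            raise ValueError("base_height must be > 0")

    def scan_of_bp(self, bp: float) -> float:
        return self.scan_offset + self.scans_per_bp * bp


def zero_noise_params(**overrides) -> SimulationParams:
    """Deterministic generator: no height noise, no size jitter."""
    return replace(
        SimulationParams(noise_cv=0.0, scale_cv=0.0, size_jitter_sd=0.0),
        **overrides,
    )


@dataclass
class SimulatedSample:
    truth: Genotype
    peak_table: PeakTable
    trace: SampleTrace | None = None


def _target_copies(genotype: Genotype, panel: PanelDefinition) -> dict[str, int]:
    """Template copy count per panel target for a diploid genotype."""
    alleles = [panel.allele(n) for n in (*genotype.alpha, *genotype.beta)]
    cnv = expected_copy_numbers(genotype.alpha, panel)
    copies: dict[str, int] = {}
    for target in panel.targets:
        if target.role == "internal_control":
            copies[target.name] = 2
        elif target.role == "cnv_reference":
            copies[target.name] = cnv[target.name]
        elif target.role == "deletion_breakpoint":
            copies[target.name] = sum(1 for a in alleles if target.name in a.markers)
        elif target.role == "point_mutation":
            copies[target.name] = sum(
                1 for a in alleles if a.point_variant == target.name
            )
        elif target.role == "wildtype_control":
            site = target.variant_link
            site_allele = panel.allele(panel.target(site).variant_link)
            copies[target.name] = sum(
                1
                for a in alleles
                if a.cluster == site_allele.cluster and a.is_wildtype_at(site)
            )
    return copies


def simulate_peak_table(
    genotype,
    panel: PanelDefinition,
    params: SimulationParams | None = None,
    seed=0,
) -> SimulatedSample:
    """Simulate one sample's peak table; deterministic given (params, seed)."""
    if isinstance(genotype, str):
        genotype = Genotype.from_label(genotype)
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    scale = float(np.exp(rng.normal(0.0, params.scale_cv)))
    copies = _target_copies(genotype, panel)
    peaks: list[Peak] = []
    for target in sorted(panel.targets, key=lambda t: (t.dye, t.expected_size)):
        c = copies[target.name]
        noise = float(np.exp(rng.normal(0.0, params.noise_cv)))
        jitter = float(rng.normal(0.0, params.size_jitter_sd))
        if c == 0:
            continue
        eff = float(params.efficiency.get(target.name, 1.0))
        height = params.base_height * eff * c * scale * noise
        if height < params.dropout_height:
            continue
        peaks.append(Peak(
            dye=target.dye,
            size=target.expected_size + jitter,
            height=height,
        ))
    table = PeakTable(
        sample_id=genotype.label(panel),
        peaks=peaks,
        metadata={"truth": genotype.label(panel), "seed": str(seed)},
    )
    return SimulatedSample(truth=genotype, peak_table=table)


def simulate_trace(
    sample: SimulatedSample,
    panel: PanelDefinition,
    params: SimulationParams | None = None,
) -> SampleTrace:
    """Render a sample's peaks as Gaussians on a constant baseline.

    The LIZ channel carries the full size standard.  Raises ``ValueError`` for
    fragment sizes whose scan position falls outside the trace.
    """
    params = params or SimulationParams()
    signals = {
        dye: np.full(params.scan_count, params.baseline_level)
        for dye in ("FAM", "VIC", "NED", "LIZ")
    }
    grid = np.arange(params.scan_count, dtype=float)

    def add_gaussian(dye: str, bp: float, height: float) -> None:
        scan = params.scan_of_bp(bp)
        if not (0 <= scan < params.scan_count):
            raise ValueError(
                f"fragment of {bp:g} bp maps to scan {scan:.0f}, outside the "
                f"trace (0..{params.scan_count - 1})"
            )
        lo = max(0, int(scan - 6 * params.sigma_peak))
        hi = min(params.scan_count, int(scan + 6 * params.sigma_peak) + 1)
        window = grid[lo:hi]
        signals[dye][lo:hi] += height * np.exp(
            -0.5 * ((window - scan) / params.sigma_peak) ** 2
        )

    for peak in sample.peak_table.peaks:
        add_gaussian(peak.dye, peak.size, peak.height)
    for bp in panel.ladder_sizes:
        add_gaussian("LIZ", float(bp), params.ladder_height)
    trace = SampleTrace(
        sample_id=sample.peak_table.sample_id,
        signals=signals,
        scan_count=params.scan_count,
    )
    sample.trace = trace
    return trace


def simulate_cohort(
    genotype_spec,
    panel: PanelDefinition,
    params: SimulationParams | None = None,
    seed=0,
) -> tuple[list[SimulatedSample], pd.DataFrame]:
    """Simulate a cohort with a truth manifest.

    ``genotype_spec`` is a list of ``(genotype_or_label, n)`` pairs.  Each
    sample gets an independent child seed of the master seed, so cohorts are
    reproducible and order-independent.
    """
    jobs: list[Genotype] = []
    for genotype, n in genotype_spec:
        if not isinstance(n, int) or n <= 0:
            raise ValueError(f"sample count must be a positive integer, got {n!r}")
        if isinstance(genotype, str):
            genotype = Genotype.from_label(genotype)
        jobs.extend([genotype] * n)
    child_seeds = np.random.SeedSequence(seed).spawn(len(jobs))
    samples: list[SimulatedSample] = []
    manifest_rows = []
    width = max(4, int(math.log10(max(len(jobs), 1))) + 1)
    for i, (genotype, child) in enumerate(zip(jobs, child_seeds)):
        sample = simulate_peak_table(genotype, panel, params, seed=child)
        sample_id = f"S{i:0{width}d}"
        sample.peak_table.sample_id = sample_id
        samples.append(sample)
        alpha = sorted(genotype.alpha)
        beta = sorted(genotype.beta)
        manifest_rows.append({
            "sample_id": sample_id,
            "alpha1": alpha[0], "alpha2": alpha[1],
            "beta1": beta[0], "beta2": beta[1],
        })
    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "alpha1", "alpha2", "beta1", "beta2"]
    )
    return samples, manifest


def table1_efficiency(genotype, panel: PanelDefinition) -> dict[str, float]:
    """Per-target efficiencies reproducing the validated classes' measured
    cohort mean ratios.

    Measured mean ratios deviate from theory in a genotype-dependent way, so
    the calibration is conditional on the sample's copy-number class: the a1
    and Y1 efficiencies are scaled by measured/theoretical for the class of
    ``genotype``; unvalidated classes get unit efficiencies.
    """
    if isinstance(genotype, str):
        genotype = Genotype.from_label(genotype)
    cls = panel.class_for_signature(class_signature(genotype.alpha, panel))
    if cls is None or not cls.validated:
        return {}
    eff: dict[str, float] = {}
    if cls.a_ratio is not None and cls.measured_mean_a is not None:
        eff["a1"] = cls.measured_mean_a / float(cls.a_ratio)
    if cls.y_ratio is not None and cls.measured_mean_y is not None:
        eff["Y1"] = cls.measured_mean_y / float(cls.y_ratio)
    return eff
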