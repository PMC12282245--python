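"""Diploid genotype calling from bound peaks.

The caller proceeds in four stages:

1. control QC — the GAPDH and AMEL internal controls must be present at or
   above the analytical threshold, otherwise the sample is UNINTERPRETABLE;
2. copy-number classification — the alpha1/alpha2 and Y1/Y2 peak-height
   ratios are matched to a diploid copy-number class in log-ratio space.
   Measurement noise on fragment peak heights is multiplicative and shared
   across amplicons of a lane, so each log ratio is modelled as Gaussian with
   a common standard deviation sqrt(2)*expected_cv; nearest-centroid
   assignment under that homoscedastic model is maximum likelihood.  The six
   empirically validated classes are preferred; model-derived "extended"
   classes are consulted only when the measurement is inconsistent (combined
   z above ``max_z``) with every validated class.  A call whose runner-up
   class lies within ``tie_loglik`` log-likelihood units (default 0.5, the
   1-sigma support interval) is refused as a tie;
3. peak evidence — allele-specific mutation peaks, deletion-breakpoint
   marker peaks and wild-type control peaks at or above the analytical
   threshold;
4. assembly — exhaustive enumeration of unordered alpha-allele and
   beta-allele pairs; a candidate genotype is consistent iff it predicts the
   called copy-number class, exactly the observed marker and mutation peaks,
   and exactly the observed wild-type-control presence pattern.  One
   consistent genotype is an OK call, several are AMBIGUOUS (all reported),
   none is NO_CALL.

NO_CALL (a quality refusal, re-testable) is distinct from UNINTERPRETABLE
(control failure, terminal for the run).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .panel import (
    CNV_TARGETS,
    Genotype,
    PanelDefinition,
    RatioClass,
    _order_pair,
    class_signature,
)
from .peakcall import (
    BindingResult,
    LadderFailure,
    assign_sizes,
    bind_peaks,
    detect_peaks,
    fit_size_ladder,
)
from .peakio import PeakTable, SampleTrace

__all__ = [
    "RatioMeasurement",
    "CnvCall",
    "EvidenceSet",
    "GenotypeCall",
    "GenotypeCatalog",
    "check_controls",
    "compute_ratios",
    "classify_cnv",
    "call_mutations",
    "collect_evidence",
    "assemble_genotype",
    "call_sample",
    "call_record",
]

NO_CALL = "NO_CALL"

# QC flag names
CONTROL_GAPDH_MISSING = "CONTROL_GAPDH_MISSING"
CONTROL_AMEL_MISSING = "CONTROL_AMEL_MISSING"
LADDER_FAILURE_FLAG = "LADDER_FAILURE"
TOTAL_ABSENCE = "TOTAL_ABSENCE"
ZYGOSITY_UNRESOLVED = "ZYGOSITY_UNRESOLVED"
LOW_CONFIDENCE_ALLELE = "LOW_CONFIDENCE_ALLELE"

FATAL_FLAGS = {CONTROL_GAPDH_MISSING, CONTROL_AMEL_MISSING, LADDER_FAILURE_FLAG}


@dataclass
class RatioMeasurement:
    """Measured alpha1/alpha2 and Y1/Y2 peak heights and ratios."""

    h_a1: float
    h_a2: float
    h_y1: float
    h_y2: float
    a_ratio: float | None
    y_ratio: float | None
    absent: frozenset[str]


@dataclass
class CnvCall:
    class_name: str               # RatioClass name or NO_CALL
    z_a: float | None = None      # standardized log-ratio distances
    z_y: float | None = None
    score: float | None = None    # combined z of the winning class
    candidates: list[tuple[str, float]] = field(default_factory=list)
    reason: str | None = None     # set when class_name == NO_CALL

    @property
    def is_call(self) -> bool:
        return self.class_name != NO_CALL


@dataclass
class EvidenceSet:
    cnv: CnvCall
    mutations_present: frozenset[str]
    markers_present: frozenset[str]
    wt_present: frozenset[str]
    wt_absent: frozenset[str]
    zygosity: dict[str, str] = field(default_factory=dict)
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class GenotypeCall:
    """The set of diploid genotypes consistent with the evidence."""

    status: str                   # OK | AMBIGUOUS | NO_CALL | UNINTERPRETABLE
    genotypes: list[Genotype] = field(default_factory=list)
    qc_flags: list[str] = field(default_factory=list)
    explanation: dict = field(default_factory=dict)
    evidence: EvidenceSet | None = None
    measurement: RatioMeasurement | None = None

    def labels(self, panel: PanelDefinition | None = None) -> list[str]:
        return [g.label(panel) for g in self.genotypes]


# ---------------------------------------------------------------------------
# QC and measurement
# ---------------------------------------------------------------------------

def check_controls(binding: BindingResult, panel: PanelDefinition) -> list[str]:
    """Internal-control QC; any returned flag is terminal downstream."""
    flags = []
    threshold = panel.analytical_min_height
    if not binding.present("GAPDH", threshold):
        flags.append(CONTROL_GAPDH_MISSING)
    if not binding.present("AMEL", threshold):
        flags.append(CONTROL_AMEL_MISSING)
    return flags


def compute_ratios(binding: BindingResult, panel: PanelDefinition) -> RatioMeasurement:
    """Dosage peak heights and ratios (0 / UNDEFINED for absent peaks)."""
    threshold = panel.analytical_min_height
    heights = {
        t: binding.height(t) if binding.present(t, threshold) else 0.0
        for t in CNV_TARGETS
    }
    absent = frozenset(t for t in CNV_TARGETS if heights[t] == 0.0)
    a = heights["a1"] / heights["a2"] if heights["a2"] > 0 else None
    y = heights["Y1"] / heights["Y2"] if heights["Y2"] > 0 else None
    return RatioMeasurement(
        h_a1=heights["a1"], h_a2=heights["a2"],
        h_y1=heights["Y1"], h_y2=heights["Y2"],
        a_ratio=a, y_ratio=y, absent=absent,
    )


def _class_distance(
    m: RatioMeasurement, cls: RatioClass, sigma: float
) -> tuple[float, float | None, float | None]:
    """Combined standardized log distance of a measurement to a class centroid,
    over the dimensions whose theoretical ratio is positive and finite."""
    z_a = z_y = None
    total = 0.0
    if cls.a_ratio is not None and cls.a_ratio > 0 and m.a_ratio:
        z_a = abs(math.log(m.a_ratio) - math.log(cls.a_ratio)) / sigma
        total += z_a * z_a
    if cls.y_ratio is not None and cls.y_ratio > 0 and m.y_ratio:
        z_y = abs(math.log(m.y_ratio) - math.log(cls.y_ratio)) / sigma
        total += z_y * z_y
    return math.sqrt(total), z_a, z_y


def classify_cnv(
    m: RatioMeasurement,
    panel: PanelDefinition,
    max_z: float | None = None,
    tie_loglik: float | None = None,
    expected_cv: float | None = None,
) -> CnvCall:
    """Assign the copy-number class of a ratio measurement.

    Parameters default to the panel's ``calling`` configuration.  See the
    module docstring for the decision rule.
    """
    calling = panel.calling
    max_z = float(calling.get("max_z", 4.0)) if max_z is None else max_z
    tie_loglik = (
        float(calling.get("tie_loglik", 0.5)) if tie_loglik is None else tie_loglik
    )
    cv = float(calling.get("expected_cv", 0.07)) if expected_cv is None else expected_cv
    sigma = math.sqrt(2.0) * cv

    compatible = [c for c in panel.ratio_classes if c.zero_pattern == m.absent]
    if not compatible:
        return CnvCall(NO_CALL, reason="ABSENCE_PATTERN_UNMATCHED")

    def decide(classes: list[RatioClass]) -> CnvCall | None:
        scored = sorted(
            ((*_class_distance(m, c, sigma), c) for c in classes),
            key=lambda item: item[0],
        )
        best_score, z_a, z_y, best = scored[0]
        if best_score > max_z:
            return None
        ranked = [(c.name, s) for s, _, _, c in scored]
        if len(scored) > 1:
            runner_score = scored[1][0]
            delta_loglik = (runner_score**2 - best_score**2) / 2.0
            if delta_loglik < tie_loglik:
                return CnvCall(
                    NO_CALL, score=best_score, candidates=ranked, reason="TIE",
                )
        return CnvCall(
            best.name, z_a=z_a, z_y=z_y, score=best_score, candidates=ranked,
        )

    validated = [c for c in compatible if c.validated]
    if validated:
        call = decide(validated)
        if call is not None:
            return call
    extended = [c for c in compatible if not c.validated]
    if extended:
        call = decide(extended)
        if call is not None:
            return call
    return CnvCall(NO_CALL, reason="ABOVE_MAX_Z")


# ---------------------------------------------------------------------------
# peak evidence
# ---------------------------------------------------------------------------

def call_mutations(binding: BindingResult, panel: PanelDefinition) -> dict[str, str]:
    """Per-variant zygosity evidence from mutation and wild-type peaks.

    Mutation peak plus its wild-type control peak -> HET; mutation peak with
    the control absent -> HOM; mutation peak with no control defined in the
    panel -> HET_OR_HOM; no mutation peak -> ABSENT.  The HOM pattern also
    arises when the second allele is a whole-gene deletion removing the
    wild-type site, so these labels are evidence, not final zygosity; assembly
    resolves them against the full candidate genotype.
    """
    threshold = panel.analytical_min_height
    out: dict[str, str] = {}
    for target in panel.targets_with_role("point_mutation"):
        if not binding.present(target.name, threshold):
            out[target.name] = "ABSENT"
            continue
        control = panel.wildtype_control_for(target.name)
        if control is None:
            out[target.name] = "HET_OR_HOM"
        elif binding.present(control.name, threshold):
            out[target.name] = "HET"
        else:
            out[target.name] = "HOM"
    return out


def collect_evidence(
    binding: BindingResult,
    panel: PanelDefinition,
    cnv: CnvCall,
    qc_flags: list[str] | None = None,
) -> EvidenceSet:
    threshold = panel.analytical_min_height
    mutations = frozenset(
        t.name
        for t in panel.targets_with_role("point_mutation")
        if binding.present(t.name, threshold)
    )
    markers = frozenset(
        t.name
        for t in panel.targets_with_role("deletion_breakpoint")
        if binding.present(t.name, threshold)
    )
    wt_targets = panel.targets_with_role("wildtype_control")
    wt_present = frozenset(
        t.name for t in wt_targets if binding.present(t.name, threshold)
    )
    wt_absent = frozenset(t.name for t in wt_targets) - wt_present
    return EvidenceSet(
        cnv=cnv,
        mutations_present=mutations,
        markers_present=markers,
        wt_present=wt_present,
        wt_absent=wt_absent,
        zygosity=call_mutations(binding, panel),
        qc_flags=list(qc_flags or []),
    )


# ---------------------------------------------------------------------------
# genotype assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _PairPrediction:
    class_name: str | None        # alpha pairs only
    markers: frozenset[str]
    mutations: frozenset[str]
    wt_present: frozenset[str]


class GenotypeCatalog:
    """Precomputed evidence predictions for every unordered allele pair.

    Alpha-side and beta-side evidence are independent (each target belongs to
    one cluster), so candidates factorize into an alpha-pair and a beta-pair
    match, keeping exhaustive assembly cheap.
    """

    def __init__(self, panel: PanelDefinition):
        self.panel = panel
        roles = {}
        for t in panel.targets:
            if t.role in ("point_mutation", "deletion_breakpoint", "wildtype_control"):
                link = t.variant_link if t.role != "wildtype_control" else (
                    panel.target(t.variant_link).variant_link
                )
                cluster = panel.allele(link).cluster if link else "beta"
                roles[t.name] = (t.role, cluster)
        self.alpha_targets = {
            role: frozenset(
                n for n, (r, c) in roles.items() if r == role and c == "alpha"
            )
            for role in ("point_mutation", "deletion_breakpoint", "wildtype_control")
        }
        self.beta_targets = {
            role: frozenset(
                n for n, (r, c) in roles.items() if r == role and c == "beta"
            )
            for role in ("point_mutation", "deletion_breakpoint", "wildtype_control")
        }
        self.alpha_pairs = self._predict_cluster("alpha")
        self.beta_pairs = self._predict_cluster("beta")

    def _predict_cluster(self, cluster: str) -> dict[tuple[str, str], _PairPrediction]:
        panel = self.panel
        names = sorted(a.name for a in panel.alleles_in_cluster(cluster))
        wt_targets = panel.targets_with_role("wildtype_control")
        out: dict[tuple[str, str], _PairPrediction] = {}
        for pair in combinations_with_replacement(names, 2):
            alleles = [panel.allele(n) for n in pair]
            markers = frozenset().union(*(a.markers for a in alleles))
            mutations = frozenset(
                a.point_variant for a in alleles if a.point_variant is not None
            )
            wt_present = frozenset(
                t.name
                for t in wt_targets
                if panel.allele(panel.target(t.variant_link).variant_link).cluster
                == cluster
                and any(a.is_wildtype_at(t.variant_link) for a in alleles)
            )
            class_name = None
            if cluster == "alpha":
                cls = panel.class_for_signature(class_signature(pair, panel))
                class_name = cls.name if cls is not None else None
            out[pair] = _PairPrediction(
                class_name=class_name,
                markers=markers,
                mutations=mutations,
                wt_present=wt_present,
            )
        return out


_catalog_cache: dict[int, GenotypeCatalog] = {}


def get_catalog(panel: PanelDefinition) -> GenotypeCatalog:
    key = id(panel)
    if key not in _catalog_cache:
        _catalog_cache[key] = GenotypeCatalog(panel)
    return _catalog_cache[key]


def assemble_genotype(
    evidence: EvidenceSet,
    panel: PanelDefinition,
    catalog: GenotypeCatalog | None = None,
) -> GenotypeCall:
    """Enumerate all diploid genotypes consistent with the evidence."""
    qc = list(evidence.qc_flags)
    if any(f in FATAL_FLAGS for f in qc):
        return GenotypeCall("UNINTERPRETABLE", qc_flags=qc, evidence=evidence)
    if not evidence.cnv.is_call:
        return GenotypeCall(
            NO_CALL,
            qc_flags=qc,
            evidence=evidence,
            explanation={"failed_constraint": f"cnv:{evidence.cnv.reason}"},
        )
    catalog = catalog or get_catalog(panel)

    obs_alpha = {
        "markers": evidence.markers_present & catalog.alpha_targets["deletion_breakpoint"],
        "mutations": evidence.mutations_present & catalog.alpha_targets["point_mutation"],
        "wt": evidence.wt_present & catalog.alpha_targets["wildtype_control"],
    }
    obs_beta = {
        "markers": evidence.markers_present & catalog.beta_targets["deletion_breakpoint"],
        "mutations": evidence.mutations_present & catalog.beta_targets["point_mutation"],
        "wt": evidence.wt_present & catalog.beta_targets["wildtype_control"],
    }

    alpha_hits = [
        pair
        for pair, pred in catalog.alpha_pairs.items()
        if pred.class_name == evidence.cnv.class_name
        and pred.markers == obs_alpha["markers"]
        and pred.mutations == obs_alpha["mutations"]
        and pred.wt_present == obs_alpha["wt"]
    ]
    beta_hits = [
        pair
        for pair, pred in catalog.beta_pairs.items()
        if pred.markers == obs_beta["markers"]
        and pred.mutations == obs_beta["mutations"]
        and pred.wt_present == obs_beta["wt"]
    ]

    def variant_count(genotype: Genotype) -> int:
        return sum(1 for n in (*genotype.alpha, *genotype.beta) if n not in ("aa", "bN"))

    # All consistent genotypes are reported (some copy-number configurations,
    # e.g. a trans deletion+triplication compound, are provably dosage-
    # identical to simpler genotypes); the most parsimonious comes first.
    genotypes = sorted(
        (
            Genotype(alpha=_order_pair(a, panel), beta=_order_pair(b, panel))
            for a in alpha_hits
            for b in beta_hits
        ),
        key=lambda g: (variant_count(g), g.label(panel)),
    )
    explanation = {
        "cnv_class": evidence.cnv.class_name,
        "alpha_candidates": [list(p) for p in sorted(alpha_hits)],
        "beta_candidates": [list(p) for p in sorted(beta_hits)],
    }
    if not genotypes:
        failed = []
        if not alpha_hits:
            failed.append("alpha_evidence")
        if not beta_hits:
            failed.append("beta_evidence")
        explanation["failed_constraint"] = "+".join(failed)
        return GenotypeCall(NO_CALL, qc_flags=qc, explanation=explanation,
                            evidence=evidence)

    if any(
        panel.allele(n).low_confidence
        for g in genotypes
        for n in (*g.alpha, *g.beta)
    ):
        qc.append(LOW_CONFIDENCE_ALLELE)
    status = "OK" if len(genotypes) == 1 else "AMBIGUOUS"
    if status == "AMBIGUOUS":
        allele_sets = {frozenset((*g.alpha, *g.beta)) - {"aa", "bN"} for g in genotypes}
        if len(allele_sets) == 1:
            qc.append(ZYGOSITY_UNRESOLVED)
    return GenotypeCall(
        status, genotypes=genotypes, qc_flags=qc, explanation=explanation,
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def call_sample(
    sample,
    panel: PanelDefinition,
    catalog: GenotypeCatalog | None = None,
) -> GenotypeCall:
    """Full pipeline on a :class:`PeakTable` or raw :class:`SampleTrace`."""
    calling = panel.calling
    if isinstance(sample, SampleTrace):
        peaks = detect_peaks(
            sample,
            min_height=float(calling.get("min_height", 200.0)),
            min_prominence=float(calling.get("min_prominence", 100.0)),
            window=int(calling.get("baseline_window", 51)),
        )
        try:
            calibration = fit_size_ladder(
                [p for p in peaks if p.dye == "LIZ"],
                panel.ladder_sizes,
                min_ladder_points=int(calling.get("min_ladder_points", 8)),
                residual_tolerance=float(
                    calling.get("ladder_residual_tolerance", 1.0)
                ),
            )
        except LadderFailure:
            return GenotypeCall("UNINTERPRETABLE", qc_flags=[LADDER_FAILURE_FLAG])
        peaks = assign_sizes(
            peaks, calibration,
            extrapolation_bp=float(calling.get("extrapolation_bp", 20.0)),
        )
    elif isinstance(sample, PeakTable):
        peaks = sample.peaks
    else:
        raise TypeError(
            f"call_sample expects a PeakTable or SampleTrace, got {type(sample)!r}"
        )

    binding = bind_peaks(peaks, panel)
    qc = check_controls(binding, panel)
    if qc:
        call = GenotypeCall("UNINTERPRETABLE", qc_flags=qc)
        call.measurement = compute_ratios(binding, panel)
        return call
    measurement = compute_ratios(binding, panel)
    cnv = classify_cnv(measurement, panel)
    evidence = collect_evidence(binding, panel, cnv, qc_flags=qc)
    call = assemble_genotype(evidence, panel, catalog)
    call.measurement = measurement
    return call


def call_record(sample_id: str, call: GenotypeCall, panel: PanelDefinition) -> dict:
    """Stable-order JSON-serializable record of one sample's call."""
    m = call.measurement
    return {
        "sample_id": sample_id,
        "status": call.status,
        "genotypes": call.labels(panel),
        "a_ratio": None if m is None else m.a_ratio,
        "y_ratio": None if m is None else m.y_ratio,
        "cnv_class": (
            call.evidence.cnv.class_name if call.evidence is not None else None
        ),
        "qc_flags": sorted(set(call.qc_flags)),
        "explanation": call.explanation,
    }
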