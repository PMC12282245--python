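"""Assay panel model: targets, alleles, copy numbers and ratio classes.

The panel describes a multiplex-PCR capillary-electrophoresis assay for
alpha/beta-thalassemia.  Deletion and triplication alleles of the alpha-globin
cluster arise from unequal crossover between homologous segments; each allele
therefore carries an integer number of amplifiable copies of the four dosage
amplicons (alpha1, alpha2, Y1, Y2), and the diploid alpha1/alpha2 and Y1/Y2
peak-height ratios identify the copy-number configuration.  Non-deletional
variants are evidenced by allele-specific amplicons (one per variant), large
deletions by breakpoint (gap-PCR style) amplicons, and heterozygous versus
homozygous point variants by paired wild-type control amplicons.

All ratio arithmetic in this module is exact (``fractions.Fraction``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "DYE_CHANNELS",
    "CNV_TARGETS",
    "TARGET_ROLES",
    "AmpliconTarget",
    "AlleleDefinition",
    "RatioClass",
    "PanelDefinition",
    "Genotype",
    "RuleViolation",
    "PanelFormatError",
    "load_panel",
    "default_panel",
    "validate_panel",
    "expected_copy_numbers",
    "expected_ratio",
    "ExpectedRatio",
    "expected_peak_set",
    "class_signature",
]

DYE_CHANNELS = ("FAM", "VIC", "NED", "LIZ")
#: dyes that may carry panel targets (LIZ is reserved for the size standard)
TARGET_DYES = ("FAM", "VIC", "NED")
CNV_TARGETS = ("a1", "a2", "Y1", "Y2")
TARGET_ROLES = (
    "cnv_reference",
    "deletion_breakpoint",
    "point_mutation",
    "wildtype_control",
    "internal_control",
)
INTERNAL_CONTROLS = {"GAPDH": "FAM", "AMEL": "VIC"}


class PanelFormatError(ValueError):
    """The panel file is structurally unusable (distinct from rule violations)."""


@dataclass(frozen=True)
class AmpliconTarget:
    """One amplicon of the multiplex: a (dye, expected size) slot."""

    name: str
    dye: str
    expected_size: float
    role: str
    variant_link: str = ""


@dataclass(frozen=True)
class AlleleDefinition:
    """One haploid allele of the alpha or beta cluster.

    ``copies`` gives the amplifiable copy count of each dosage amplicon on the
    chromosome carrying this allele (alpha cluster only).  ``markers`` are the
    breakpoint amplicons that amplify from this allele, ``point_variant`` the
    allele-specific mutation amplicon.  ``wt_suppressing`` alleles (whole-gene
    deletions) contribute no wild-type sequence at any point-variant site of
    their cluster.
    """

    name: str
    cluster: str  # "alpha" | "beta"
    copies: Mapping[str, int] | None = None
    markers: frozenset[str] = frozenset()
    point_variant: str | None = None
    wt_suppressing: bool = False
    low_confidence: bool = False

    def is_wildtype_at(self, mutation_target: str) -> bool:
        """Whether this allele carries wild-type sequence at a variant site."""
        if self.wt_suppressing:
            return False
        return self.point_variant != mutation_target


@dataclass
class RatioClass:
    """A diploid copy-number configuration of the dosage amplicons.

    ``a_ratio``/``y_ratio`` are exact theoretical ratios (``None`` when the
    denominator copy sum is zero); ``zero_pattern`` is the set of dosage
    amplicons with zero total copies.  Validated classes carry the empirical
    cohort means/SDs of the measured ratios; extended classes are derived from
    the copy model.
    """

    name: str
    a_ratio: Fraction | None
    y_ratio: Fraction | None
    zero_pattern: frozenset[str]
    validated: bool = False
    measured_mean_a: float | None = None
    measured_sd_a: float | None = None
    measured_mean_y: float | None = None
    measured_sd_y: float | None = None

    @property
    def signature(self) -> tuple[frozenset[str], Fraction | None, Fraction | None]:
        return (self.zero_pattern, self.a_ratio, self.y_ratio)


@dataclass(frozen=True)
class Genotype:
    """A diploid genotype: unordered alpha-allele and beta-allele pairs."""

    alpha: tuple[str, str]
    beta: tuple[str, str] = ("bN", "bN")

    def label(self, panel: "PanelDefinition | None" = None) -> str:
        alpha = _order_pair(self.alpha, panel)
        beta = _order_pair(self.beta, panel)
        return f"{alpha[0]}/{alpha[1]};{beta[0]}/{beta[1]}"

    @staticmethod
    def from_label(label: str) -> "Genotype":
        try:
            alpha_part, beta_part = label.split(";")
            a1, a2 = alpha_part.split("/")
            b1, b2 = beta_part.split("/")
        except ValueError as exc:
            raise ValueError(
                f"genotype label {label!r} is not 'a/a;b/b'"
            ) from exc
        return Genotype(alpha=(a1, a2), beta=(b1, b2))


def _severity_rank(name: str, panel: "PanelDefinition | None") -> tuple[int, str]:
    """Display order within a pair: variants first, whole deletions late,
    the normal allele last (matching the conventional 'variant/normal' and
    'point-variant/--deletion' genotype styles)."""
    if name in ("aa", "bN"):
        return (3, name)
    if panel is not None and name in panel.alleles_by_name:
        allele = panel.alleles_by_name[name]
        if allele.wt_suppressing:
            return (2, name)
        if allele.point_variant is not None:
            return (0, name)
        return (1, name)
    return (1, name)


def _order_pair(pair: Sequence[str], panel: "PanelDefinition | None") -> tuple[str, str]:
    ordered = sorted(pair, key=lambda n: _severity_rank(n, panel))
    return (ordered[0], ordered[1])


@dataclass(frozen=True)
class RuleViolation:
    code: str
    message: str


ValidationReport = list[RuleViolation]


@dataclass
class PanelDefinition:
    """A parsed, queryable assay panel."""

    targets: list[AmpliconTarget]
    alleles: list[AlleleDefinition]
    ratio_classes: list[RatioClass]
    min_same_dye_spacing: float = 3.0
    size_tolerance: float = 1.4
    analytical_min_height: float = 200.0
    calling: dict = field(default_factory=dict)
    ladder_sizes: tuple[float, ...] = ()
    version: str = "unversioned"

    def __post_init__(self) -> None:
        self.targets_by_name = {t.name: t for t in self.targets}
        self.alleles_by_name = {a.name: a for a in self.alleles}
        self._class_by_signature = {c.signature: c for c in self.ratio_classes}

    # -- convenience views -------------------------------------------------
    def allele(self, name: str) -> AlleleDefinition:
        try:
            return self.alleles_by_name[name]
        except KeyError:
            raise KeyError(f"unknown allele {name!r}") from None

    def target(self, name: str) -> AmpliconTarget:
        try:
            return self.targets_by_name[name]
        except KeyError:
            raise KeyError(f"unknown target {name!r}") from None

    def targets_with_role(self, role: str) -> list[AmpliconTarget]:
        return [t for t in self.targets if t.role == role]

    def alleles_in_cluster(self, cluster: str) -> list[AlleleDefinition]:
        return [a for a in self.alleles if a.cluster == cluster]

    def variant_allele_names(self) -> list[str]:
        return [a.name for a in self.alleles if a.name not in ("aa", "bN")]

    def class_for_signature(self, signature) -> RatioClass | None:
        return self._class_by_signature.get(signature)

    def wildtype_control_for(self, mutation_target: str) -> AmpliconTarget | None:
        for t in self.targets:
            if t.role == "wildtype_control" and t.variant_link == mutation_target:
                return t
        return None


# ---------------------------------------------------------------------------
# copy-number model
# ---------------------------------------------------------------------------

def _resolve_allele(allele, panel: PanelDefinition) -> AlleleDefinition:
    if isinstance(allele, AlleleDefinition):
        return allele
    return panel.allele(allele)


def expected_copy_numbers(alpha_pair, panel: PanelDefinition) -> dict[str, int]:
    """Summed dosage-amplicon copy numbers for a diploid alpha-allele pair."""
    out = dict.fromkeys(CNV_TARGETS, 0)
    for name in alpha_pair:
        allele = _resolve_allele(name, panel)
        if allele.cluster != "alpha":
            raise ValueError(f"allele {allele.name!r} is not an alpha allele")
        if allele.copies is None:
            raise ValueError(f"alpha allele {allele.name!r} has no copy map")
        for t in CNV_TARGETS:
            if t not in allele.copies:
                raise ValueError(
                    f"alpha allele {allele.name!r} missing copy count for {t!r}"
                )
            out[t] += allele.copies[t]
    return out


@dataclass(frozen=True)
class ExpectedRatio:
    """Theoretical alpha1/alpha2 and Y1/Y2 ratios; ``None`` = undefined
    (denominator has zero copies)."""

    a_ratio: Fraction | None
    y_ratio: Fraction | None
    total_absence: bool = False


def expected_ratio(alpha_pair, panel: PanelDefinition) -> ExpectedRatio:
    """Exact theoretical peak-height ratios for an alpha-allele pair."""
    copies = expected_copy_numbers(alpha_pair, panel)
    a = Fraction(copies["a1"], copies["a2"]) if copies["a2"] else None
    y = Fraction(copies["Y1"], copies["Y2"]) if copies["Y2"] else None
    total = all(copies[t] == 0 for t in CNV_TARGETS)
    return ExpectedRatio(a_ratio=a, y_ratio=y, total_absence=total)


def class_signature(alpha_pair, panel: PanelDefinition):
    """(zero-copy pattern, a ratio, y ratio) identifying a ratio class."""
    copies = expected_copy_numbers(alpha_pair, panel)
    pattern = frozenset(t for t in CNV_TARGETS if copies[t] == 0)
    a = Fraction(copies["a1"], copies["a2"]) if copies["a2"] else None
    y = Fraction(copies["Y1"], copies["Y2"]) if copies["Y2"] else None
    return (pattern, a, y)


def expected_peak_set(genotype: Genotype, panel: PanelDefinition) -> set[str]:
    """Target names with positive expected signal for a diploid genotype."""
    alleles = [_resolve_allele(n, panel) for n in (*genotype.alpha, *genotype.beta)]
    for allele, cluster in zip(alleles, ("alpha", "alpha", "beta", "beta")):
        if allele.cluster != cluster:
            raise ValueError(
                f"allele {allele.name!r} is not in the {cluster} cluster"
            )
    present: set[str] = set(INTERNAL_CONTROLS)
    copies = expected_copy_numbers(genotype.alpha, panel)
    present.update(t for t in CNV_TARGETS if copies[t] > 0)
    for allele in alleles:
        present.update(allele.markers)
        if allele.point_variant is not None:
            present.add(allele.point_variant)
    for target in panel.targets_with_role("wildtype_control"):
        site = target.variant_link
        site_cluster = panel.target(site).variant_link
        cluster = panel.allele(site_cluster).cluster if site_cluster else "beta"
        cluster_alleles = [a for a in alleles if a.cluster == cluster]
        if any(a.is_wildtype_at(site) for a in cluster_alleles):
            present.add(target.name)
    return present


# ---------------------------------------------------------------------------
# ratio-class generation
# ---------------------------------------------------------------------------

def _unordered_pairs(names: Sequence[str]) -> Iterable[tuple[str, str]]:
    for i, a in enumerate(names):
        for b in names[i:]:
            yield (a, b)


def _class_name_for(pairs: list[tuple[str, str]], panel_alleles: dict) -> str:
    """Canonical label for an extended class: prefer the representative pair
    with fewest variant alleles and no low-confidence allele."""

    def pair_key(pair):
        n_variant = sum(1 for n in pair if n != "aa")
        low_conf = any(panel_alleles[n].low_confidence for n in pair)
        return (n_variant, low_conf, tuple(sorted(pair)))

    best = min(pairs, key=pair_key)
    return "/".join(sorted(best, key=lambda n: (n == "aa", n)))


def build_ratio_classes(
    alleles: Sequence[AlleleDefinition], validated_specs: Sequence[dict]
) -> list[RatioClass]:
    """Enumerate every diploid copy-number signature expressible by the panel's
    alpha alleles; attach empirical stats to the validated ones."""
    by_name = {a.name: a for a in alleles if a.cluster == "alpha"}

    def signature_of(pair):
        sums = dict.fromkeys(CNV_TARGETS, 0)
        for n in pair:
            for t in CNV_TARGETS:
                sums[t] += by_name[n].copies[t]
        pattern = frozenset(t for t in CNV_TARGETS if sums[t] == 0)
        a = Fraction(sums["a1"], sums["a2"]) if sums["a2"] else None
        y = Fraction(sums["Y1"], sums["Y2"]) if sums["Y2"] else None
        return (pattern, a, y)

    validated: dict = {}
    for spec in validated_specs:
        pair = tuple(spec["alleles"])
        sig = signature_of(pair)
        name = "/".join(sorted(pair, key=lambda n: (n == "aa", n)))
        validated[sig] = RatioClass(
            name=name,
            a_ratio=sig[1],
            y_ratio=sig[2],
            zero_pattern=sig[0],
            validated=True,
            measured_mean_a=spec.get("measured_mean_a"),
            measured_sd_a=spec.get("measured_sd_a"),
            measured_mean_y=spec.get("measured_mean_y"),
            measured_sd_y=spec.get("measured_sd_y"),
        )

    groups: dict[tuple, list[tuple[str, str]]] = {}
    for pair in _unordered_pairs(sorted(by_name)):
        groups.setdefault(signature_of(pair), []).append(pair)

    classes = []
    for sig, pairs in groups.items():
        if sig in validated:
            classes.append(validated[sig])
        else:
            classes.append(
                RatioClass(
                    name=_class_name_for(pairs, by_name),
                    a_ratio=sig[1],
                    y_ratio=sig[2],
                    zero_pattern=sig[0],
                    validated=False,
                )
            )
    missing = [v.name for s, v in validated.items() if s not in groups]
    if missing:
        raise PanelFormatError(
            f"validated classes {missing} not expressible by the allele table"
        )
    return sorted(classes, key=lambda c: (not c.validated, c.name))


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------

def _parse_target(raw: dict) -> AmpliconTarget:
    try:
        name = str(raw["name"])
        dye = str(raw["dye"])
        size = float(raw["expected_size"])
        role = str(raw["role"])
    except (KeyError, TypeError, ValueError) as exc:
        raise PanelFormatError(f"malformed target entry {raw!r}: {exc}") from exc
    if dye not in DYE_CHANNELS:
        raise PanelFormatError(f"target {name!r}: unknown dye {dye!r}")
    if role not in TARGET_ROLES:
        raise PanelFormatError(f"target {name!r}: unknown role {role!r}")
    return AmpliconTarget(
        name=name, dye=dye, expected_size=size, role=role,
        variant_link=str(raw.get("variant_link", "")),
    )


def _parse_allele(raw: dict) -> AlleleDefinition:
    try:
        name = str(raw["name"])
        cluster = str(raw["cluster"])
    except (KeyError, TypeError) as exc:
        raise PanelFormatError(f"malformed allele entry {raw!r}: {exc}") from exc
    if cluster not in ("alpha", "beta"):
        raise PanelFormatError(f"allele {name!r}: unknown cluster {cluster!r}")
    copies = raw.get("copies")
    if copies is not None:
        copies = {str(k): int(v) for k, v in copies.items()}
        if any(v < 0 for v in copies.values()):
            raise PanelFormatError(f"allele {name!r}: negative copy count")
    return AlleleDefinition(
        name=name,
        cluster=cluster,
        copies=copies,
        markers=frozenset(str(m) for m in raw.get("markers", [])),
        point_variant=raw.get("point_variant"),
        wt_suppressing=bool(raw.get("wt_suppressing", False)),
        low_confidence=bool(raw.get("low_confidence", False)),
    )


def load_panel(path=None) -> PanelDefinition:
    """Load a panel YAML (the shipped default when ``path`` is None)."""
    if path is None:
        text = (
            resources.files("cefacall").joinpath("data/default_panel.yaml")
        ).read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise PanelFormatError(f"panel file is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise PanelFormatError("panel file must be a mapping")
    for section in ("targets", "alleles"):
        if section not in raw or not isinstance(raw[section], list):
            raise PanelFormatError(f"panel file missing {section!r} list")

    targets = [_parse_target(t) for t in raw["targets"]]
    alleles = [_parse_allele(a) for a in raw["alleles"]]
    thresholds = raw.get("thresholds", {}) or {}
    try:
        classes = build_ratio_classes(alleles, raw.get("validated_classes", []) or [])
    except (KeyError, TypeError) as exc:
        raise PanelFormatError(f"cannot build ratio classes: {exc}") from exc
    ladder = tuple(float(s) for s in (raw.get("size_standard", {}) or {}).get("sizes", ()))
    return PanelDefinition(
        targets=targets,
        alleles=alleles,
        ratio_classes=classes,
        min_same_dye_spacing=float(thresholds.get("min_same_dye_spacing", 3.0)),
        size_tolerance=float(thresholds.get("size_tolerance", 1.4)),
        analytical_min_height=float(thresholds.get("analytical_min_height", 200.0)),
        calling=dict(raw.get("calling", {}) or {}),
        ladder_sizes=ladder,
        version=str(raw.get("panel_version", "unversioned")),
    )


def default_panel() -> PanelDefinition:
    return load_panel(None)


def validate_panel(panel: PanelDefinition) -> ValidationReport:
    """Check the panel against the assay design rules; empty report = valid."""
    report: ValidationReport = []

    seen: set[str] = set()
    for t in panel.targets:
        if t.name in seen:
            report.append(RuleViolation("DUPLICATE_NAME", f"duplicate target name {t.name!r}"))
        seen.add(t.name)

    for t in panel.targets:
        if not (80.0 <= t.expected_size <= 600.0):
            report.append(RuleViolation(
                "SIZE_RANGE",
                f"target {t.name!r} size {t.expected_size} bp out of 80-600 range",
            ))
        if t.dye == "LIZ":
            report.append(RuleViolation(
                "LIZ_TARGET", f"target {t.name!r} assigned to the LIZ ladder channel"
            ))

    for dye in TARGET_DYES:
        sized = sorted(
            (t for t in panel.targets if t.dye == dye), key=lambda t: t.expected_size
        )
        for left, right in zip(sized, sized[1:]):
            gap = right.expected_size - left.expected_size
            if gap < panel.min_same_dye_spacing:
                report.append(RuleViolation(
                    "DYE_SPACING",
                    f"same-dye spacing < {panel.min_same_dye_spacing} bp between "
                    f"{left.name!r} and {right.name!r} ({gap:g} bp, {dye})",
                ))

    mutation_names = {t.name for t in panel.targets_with_role("point_mutation")}
    for t in panel.targets_with_role("wildtype_control"):
        if t.variant_link not in mutation_names:
            report.append(RuleViolation(
                "WT_WITHOUT_MUTATION",
                f"wild-type control {t.name!r} references no point-mutation "
                f"target ({t.variant_link!r})",
            ))

    for name, dye in INTERNAL_CONTROLS.items():
        t = panel.targets_by_name.get(name)
        if t is None or t.role != "internal_control" or t.dye != dye:
            report.append(RuleViolation(
                "MISSING_INTERNAL_CONTROL",
                f"internal control {name!r} ({dye}) missing or misconfigured",
            ))

    for allele in panel.alleles_in_cluster("alpha"):
        if allele.copies is None or set(allele.copies) != set(CNV_TARGETS):
            report.append(RuleViolation(
                "INCOMPLETE_COPY_MAP",
                f"alpha allele {allele.name!r} lacks a complete "
                f"{{a1, a2, Y1, Y2}} copy map",
            ))
        elif any(v not in (0, 1, 2) for v in allele.copies.values()):
            report.append(RuleViolation(
                "INCOMPLETE_COPY_MAP",
                f"alpha allele {allele.name!r} has copy counts outside {{0,1,2}}",
            ))

    seen_alleles: set[str] = set()
    for a in panel.alleles:
        if a.name in seen_alleles:
            report.append(RuleViolation("DUPLICATE_NAME", f"duplicate allele name {a.name!r}"))
        seen_alleles.add(a.name)

    return report
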