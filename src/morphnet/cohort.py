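"""Synthetic cohorts with known ground truth.

Emulates the data structure of a three-group cross-sectional surface
morphometry study (heroin-abstinent HA, methamphetamine-abstinent MA,
healthy controls HC; default sizes 26/24/32): per-subject vertex-wise
values of four morphometric features on a shared parcellation, group
labels, and clinical covariates.  Regional group effects and monotone
clinical-morphology associations are planted with known magnitudes so
every downstream stage — density estimation, similarity networks, graph
metrics, permutation statistics — can be validated against ground truth.

The generative model, per feature and ROI r:

* a fixed per-ROI baseline location ``loc_r`` (drawn once per design
  around the feature's typical value — the shared template surface),
* a subject-level regional mean ``mu_sr = loc_r + between_sd * eta_sr``,
* vertex values ``N(mu_sr, within_sd)`` (optionally a symmetric
  two-component mixture, so the density machinery also meets
  non-Gaussian shapes).

A location-shift effect of magnitude ``d`` moves the target group's
``mu_sr`` by ``d * sd(regional mean)`` where
``sd(regional mean) = sqrt(between_sd^2 + within_sd^2 / m_r)`` — i.e.
``d`` is Cohen's d on subject-level regional means, the quantity the
downstream tests compare.

Clinical covariates have lognormal marginals (drug-use and symptom
scales are right-skewed and non-negative, which also exercises the
Shapiro-Wilk reporting on its intended branch).  Planted associations
couple a clinical variable to a morphometric summary through a latent
Gaussian copula: Spearman targets are rank-based, so the coupling is
applied on normal scores and mapped back through the declared marginal,
leaving the marginal family intact.  The latent correlation solves
``rho_S = (6/pi) arcsin(rho_latent/2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .features import FEATURES, VertexFeatureMap, regional_mean

__all__ = [
    "CohortConfigError",
    "FeatureBaseline",
    "PlantedEffect",
    "PlantedAssociation",
    "ClinicalMarginal",
    "CohortDesign",
    "SubjectRecord",
    "default_baselines",
    "default_clinical_marginals",
    "generate_cohort",
    "plant_clinical",
    "cohort_regional_means",
]

#: clinical covariates collected for the patient groups
CLINICAL_VARIABLES = (
    "abstinence_days",
    "abuse_years",
    "freq_per_day",
    "dose_per_use_g",
    "dose_per_day_g",
    "hama",
    "hamd",
    "cigarettes_per_day",
)

#: variables undefined for healthy controls (set to zero there)
_PATIENT_ONLY = (
    "abstinence_days",
    "abuse_years",
    "freq_per_day",
    "dose_per_use_g",
    "dose_per_day_g",
)


class CohortConfigError(ValueError):
    """A design references an unknown ROI, feature, or group."""


@dataclass(frozen=True)
class FeatureBaseline:
    """Location/scale parameters of one feature's within-ROI distribution.

    ``within_sd`` is the vertex-level scatter inside an ROI, ``between_sd``
    the subject-to-subject scatter of the regional mean, ``roi_spread`` the
    across-ROI spread of baseline locations.  ``mixture_separation > 0``
    turns the vertex distribution into an equal-weight two-component
    Gaussian mixture with components at ``loc +- separation/2`` (same mean,
    non-Gaussian shape).
    """

    loc: float
    within_sd: float
    between_sd: float
    roi_spread: float
    mixture_separation: float = 0.0

    @property
    def within_var_effective(self) -> float:
        return self.within_sd**2 + self.mixture_separation**2 / 4.0


def default_baselines() -> dict:
    """Typical surface-morphometry scales: CT and SD in mm, FD and GI unitless."""
    return {
        "CT": FeatureBaseline(loc=2.5, within_sd=0.30, between_sd=0.08, roi_spread=0.25),
        "FD": FeatureBaseline(loc=2.55, within_sd=0.08, between_sd=0.02, roi_spread=0.05),
        "GI": FeatureBaseline(loc=2.7, within_sd=0.35, between_sd=0.08, roi_spread=0.20),
        "SD": FeatureBaseline(loc=1.3, within_sd=0.45, between_sd=0.10, roi_spread=0.30),
    }


@dataclass(frozen=True)
class ClinicalMarginal:
    """Lognormal marginal: ``exp(N(log(median), sigma))``."""

    median: float
    sigma: float

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return np.exp(math.log(self.median) + self.sigma * ndtri(u))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.ppf(rng.uniform(size=n))


def default_clinical_marginals() -> dict:
    """Right-skewed marginals roughly on the scale of early-abstinence cohorts."""
    return {
        "abstinence_days": ClinicalMarginal(60.0, 0.6),
        "abuse_years": ClinicalMarginal(5.5, 0.5),
        "freq_per_day": ClinicalMarginal(2.5, 0.6),
        "dose_per_use_g": ClinicalMarginal(0.2, 0.9),
        "dose_per_day_g": ClinicalMarginal(0.4, 0.8),
        "hama": ClinicalMarginal(5.0, 0.7),
        "hamd": ClinicalMarginal(5.0, 0.7),
        "cigarettes_per_day": ClinicalMarginal(15.0, 0.5),
    }


@dataclass(frozen=True)
class PlantedEffect:
    """A known group difference in one ROI x feature.

    ``kind``: ``"location"`` shifts the target group's regional mean by
    ``magnitude`` standard deviations of the regional mean (Cohen's d; d=0
    reproduces the baseline exactly); ``"scale"`` multiplies the
    vertex-level scatter by ``magnitude``; ``"shape"`` adds a two-component
    mixture of separation ``magnitude * within_sd`` (mean-preserving).
    """

    roi_id: int
    feature: str
    groups: tuple
    magnitude: float
    kind: str = "location"

    def __post_init__(self):
        if isinstance(self.groups, str):
            object.__setattr__(self, "groups", (self.groups,))
        else:
            object.__setattr__(self, "groups", tuple(self.groups))
        if self.kind not in ("location", "scale", "shape"):
            raise CohortConfigError(f"unknown effect kind {self.kind!r}")
        if not np.isfinite(self.magnitude):
            raise CohortConfigError("effect magnitude must be finite")


@dataclass(frozen=True)
class PlantedAssociation:
    """A known monotone association between a clinical variable and a
    morphometric summary within one group.

    ``summary`` is ``"regional_mean"`` or ``"nodal_efficiency"`` (the
    latter is the across-sparsity AUC of the node's efficiency and needs a
    network configuration when planted).  ``rho`` is the target Spearman
    correlation, |rho| < 1.
    """

    variable: str
    roi_id: int
    feature: str
    rho: float
    group: str
    summary: str = "regional_mean"

    def __post_init__(self):
        if not (abs(self.rho) < 1.0):
            raise CohortConfigError(
                f"association rho must satisfy |rho| < 1, got {self.rho}"
            )
        if self.summary not in ("regional_mean", "nodal_efficiency"):
            raise CohortConfigError(f"unknown summary {self.summary!r}")


@dataclass(frozen=True)
class CohortDesign:
    """Full specification of a synthetic cohort; the seed determines the
    output byte-for-byte."""

    groups: tuple = (("HA", 26), ("MA", 24), ("HC", 32))
    n_roi: int = 210
    vertices_per_roi: tuple = (50, 500)
    features: tuple = FEATURES
    baselines: dict = field(default_factory=default_baselines)
    effects: tuple = ()
    clinical_model: tuple = ()
    clinical_marginals: dict = field(default_factory=default_clinical_marginals)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple((str(g), int(n)) for g, n in self.groups))
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "effects", tuple(self.effects))
        object.__setattr__(self, "clinical_model", tuple(self.clinical_model))
        self.validate()

    def validate(self) -> None:
        if self.n_roi < 2:
            raise CohortConfigError("n_roi must be >= 2")
        if any(n < 2 for _, n in self.groups):
            raise CohortConfigError("every group needs >= 2 subjects")
        lo, hi = self.vertices_per_roi
        if lo < 2 or hi < lo:
            raise CohortConfigError("vertices_per_roi must be a range with lo >= 2")
        group_names = {g for g, _ in self.groups}
        for f in self.features:
            if f not in self.baselines:
                raise CohortConfigError(f"feature {f!r} has no baseline parameters")
        for eff in self.effects:
            if not (1 <= eff.roi_id <= self.n_roi):
                raise CohortConfigError(
                    f"planted effect references unknown ROI {eff.roi_id} "
                    f"(valid: 1..{self.n_roi})"
                )
            if eff.feature not in self.features:
                raise CohortConfigError(
                    f"planted effect references unknown feature {eff.feature!r}"
                )
            for g in eff.groups:
                if g not in group_names:
                    raise CohortConfigError(
                        f"planted effect references unknown group {g!r}"
                    )
        for assoc in self.clinical_model:
            if not (1 <= assoc.roi_id <= self.n_roi):
                raise CohortConfigError(
                    f"association references unknown ROI {assoc.roi_id}"
                )
            if assoc.feature not in self.features:
                raise CohortConfigError(
                    f"association references unknown feature {assoc.feature!r}"
                )
            if assoc.group not in group_names:
                raise CohortConfigError(
                    f"association references unknown group {assoc.group!r}"
                )
            if assoc.variable not in CLINICAL_VARIABLES:
                raise CohortConfigError(
                    f"association references unknown clinical variable "
                    f"{assoc.variable!r}"
                )

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.groups)


@dataclass
class SubjectRecord:
    """One synthetic participant: group label, clinical covariates, and one
    vertex feature map per morphometric feature."""

    subject_id: str
    group: str
    clinical: dict
    maps: dict

    def feature_map(self, feature: str) -> VertexFeatureMap:
        return self.maps[feature]


def _regional_sd(baseline: FeatureBaseline, m: int) -> float:
    return math.sqrt(baseline.between_sd**2 + baseline.within_var_effective / m)


def generate_cohort(design: CohortDesign) -> list:
    """Draw a full cohort from the design; deterministic given the seed.

    Vertex counts per ROI are drawn once and shared by all subjects (the
    parcellation lives on a common template surface).  Planted effects
    modify the designated group's distributions; planted clinical
    associations are applied afterwards through :func:`plant_clinical`.
    """
    design.validate()
    ss = np.random.SeedSequence(design.seed)
    s_struct, s_subj, s_clin = ss.spawn(3)
    rng_struct = np.random.default_rng(s_struct)

    lo, hi = design.vertices_per_roi
    m = rng_struct.integers(lo, hi + 1, size=design.n_roi)
    total = int(m.sum())
    roi_labels = np.repeat(np.arange(1, design.n_roi + 1), m)

    roi_loc = {}
    for f in design.features:
        b = design.baselines[f]
        roi_loc[f] = b.loc + b.roi_spread * rng_struct.standard_normal(design.n_roi)

    # per-(feature, group) modifications from planted effects
    loc_shift = {(f, g): np.zeros(design.n_roi) for f in design.features
                 for g, _ in design.groups}
    scale_mult = {(f, g): np.ones(design.n_roi) for f in design.features
                  for g, _ in design.groups}
    mix_sep = {(f, g): np.zeros(design.n_roi) for f in design.features
               for g, _ in design.groups}
    for f in design.features:
        b = design.baselines[f]
        for g, _ in design.groups:
            if b.mixture_separation > 0:
                mix_sep[(f, g)] += b.mixture_separation
    for eff in design.effects:
        b = design.baselines[eff.feature]
        r = eff.roi_id - 1
        for g in eff.groups:
            if eff.kind == "location":
                loc_shift[(eff.feature, g)][r] += eff.magnitude * _regional_sd(b, int(m[r]))
            elif eff.kind == "scale":
                scale_mult[(eff.feature, g)][r] *= eff.magnitude
            else:  # shape
                mix_sep[(eff.feature, g)][r] += abs(eff.magnitude) * b.within_sd

    rng_subj = np.random.default_rng(s_subj)
    rng_clin = np.random.default_rng(s_clin)
    records = []
    sid = 0
    for group, n in design.groups:
        for _ in range(n):
            sid += 1
            subject_id = f"sub-{sid:03d}"
            maps = {}
            for f in design.features:
                b = design.baselines[f]
                mu = (roi_loc[f]
                      + b.between_sd * rng_subj.standard_normal(design.n_roi)
                      + loc_shift[(f, group)])
                sd = b.within_sd * scale_mult[(f, group)]
                mu_vec = np.repeat(mu, m)
                sd_vec = np.repeat(sd, m)
                values = mu_vec + sd_vec * rng_subj.standard_normal(total)
                sep = mix_sep[(f, group)]
                if np.any(sep > 0):
                    comp = rng_subj.integers(0, 2, size=total) * 2 - 1
                    values = values + comp * np.repeat(sep, m) / 2.0
                maps[f] = VertexFeatureMap(subject_id, f, values, roi_labels)
            clinical = {}
            for var in CLINICAL_VARIABLES:
                if group == "HC" and var in _PATIENT_ONLY:
                    clinical[var] = 0.0
                else:
                    marg = design.clinical_marginals[var]
                    if group == "HC":
                        marg = ClinicalMarginal(marg.median / 2.5, marg.sigma)
                    clinical[var] = float(marg.sample(rng_clin, 1)[0])
            records.append(SubjectRecord(subject_id, group, clinical, maps))
    if design.clinical_model:
        plant_clinical(records, design.clinical_model,
                       marginals=design.clinical_marginals, rng=rng_clin)
    return records


def _summary_values(records, assoc: PlantedAssociation, network_config=None) -> np.ndarray:
    if assoc.summary == "regional_mean":
        return np.array([regional_mean(r.maps[assoc.feature], assoc.roi_id)
                         for r in records])
    # nodal efficiency AUC: build each subject's network for the feature
    from .pipeline import subject_nodal_efficiency_auc
    return np.array([
        subject_nodal_efficiency_auc(r, assoc.feature, config=network_config)[assoc.roi_id]
        for r in records
    ])


def plant_clinical(records, associations, marginals=None, seed=None, rng=None,
                   network_config=None):
    """Re-draw targeted clinical variables so each attains its Spearman target.

    For each association the targeted group's morphometric summary is
    ranked, converted to normal scores, mixed with independent Gaussian
    noise at the latent correlation ``2 sin(pi rho / 6)``, and mapped
    through the variable's declared marginal — the marginal family is
    preserved exactly and the sample Spearman correlation converges to
    ``rho`` as n grows.  Returns the records (modified in place).
    """
    if marginals is None:
        marginals = default_clinical_marginals()
    if rng is None:
        rng = np.random.default_rng(seed)
    for assoc in associations:
        if not (abs(assoc.rho) < 1.0):
            raise CohortConfigError("association rho must satisfy |rho| < 1")
        subs = [r for r in records if r.group == assoc.group]
        if not subs:
            raise CohortConfigError(
                f"association targets group {assoc.group!r} with no subjects"
            )
        s = _summary_values(subs, assoc, network_config=network_config)
        n = len(subs)
        z_s = ndtri((rankdata(s) - 0.5) / n)
        rho_lat = 2.0 * math.sin(math.pi * assoc.rho / 6.0)
        z_c = rho_lat * z_s + math.sqrt(1.0 - rho_lat**2) * rng.standard_normal(n)
        u = np.clip(ndtr(z_c), 1e-12, 1 - 1e-12)
        vals = marginals[assoc.variable].ppf(u)
        for r, v in zip(subs, vals):
            r.clinical[assoc.variable] = float(v)
    return records


def cohort_regional_means(records, feature: str, roi_ids=None) -> np.ndarray:
    """Matrix of regional means, shape (n_roi, n_subjects)."""
    if roi_ids is None:
        roi_ids = records[0].maps[feature].roi_ids
    roi_ids = np.asarray(roi_ids, int)
    out = np.empty((len(roi_ids), len(records)))
    for j, rec in enumerate(records):
        vmap = rec.maps[feature]
        minlength = int(roi_ids.max()) + 1
        counts = np.bincount(vmap.roi_labels, minlength=minlength)
        if np.any(counts[roi_ids] == 0):
            empty = roi_ids[counts[roi_ids] == 0].tolist()
            raise CohortConfigError(
                f"ROIs {empty} have no vertices for {rec.subject_id}/{feature}"
            )
        sums = np.bincount(vmap.roi_labels, weights=vmap.values, minlength=minlength)
        out[:, j] = sums[roi_ids] / counts[roi_ids]
    return out
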