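"""Synthetic lymph-node cohort generator.

Real per-node measurement tables of this kind are rarely shareable, so this
module generates cohorts with the statistical structure the analysis
pipeline assumes: group-specific per-sequence ADC distributions calibrated
to published median/IQR summaries, correlated within-patient reference
measurements (three contralateral benign nodes and one muscle region),
a second reader with calibrated additive measurement noise, and short-axis
diameter / Node-RADS co-variables.

Distributions default to lognormal — ADC values are strictly positive and
reported IQRs are right-skewed — calibrated in closed form so the target
median is reproduced exactly and the IQR exactly whenever the target IQR is
multiplicatively symmetric about the median (any asymmetry is reported as a
calibration residual). A truncated-normal family is available for
sensitivity checks.

Within-patient correlation comes from one standard-normal patient effect
``z`` shared by all of a patient's draws: a measurement with calibrated
log-scale ``sigma`` is drawn as ``exp(mu + sqrt(f)*sigma*z +
sqrt(1-f)*sigma*eps)`` where ``f`` is ``intra_patient_sd_fraction``. This
leaves each metric's marginal distribution at its calibrated target while
inducing correlation between a patient's nodal, contralateral and muscle
values — the structure the intra-patient ratios exploit.

The generator-truth optimal cut-off for any benign/metastatic spec pair is
available in closed form (:func:`implied_optimal_cutoff`), which is the
yardstick recovery tests score the pipeline against.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import (
    Basin,
    CohortGroup,
    LymphNodeRecord,
    Reader,
    ReferencePanel,
    Sequence,
    TruthStatus,
)
from .performance import Orientation

__all__ = [
    "MetricDistributionSpec",
    "SyntheticCohortConfig",
    "ImpliedCutoff",
    "calibrate_lognormal",
    "generate_cohort",
    "implied_optimal_cutoff",
    "implied_ratio_spec",
    "default_config",
    "recovery_config",
    "reference_structure_cohort",
]

_Z75 = stats.norm.ppf(0.75)  # 0.6744897501960817


def calibrate_lognormal(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """Closed-form lognormal parameters hitting a target median and IQR.

    Returns ``(location, scale)`` of the underlying normal: location
    ``ln(median)`` and scale ``ln(q3/q1) / (2 * z_0.75)``. The resulting
    distribution's median equals the target exactly; its IQR equals the
    target exactly iff ``q1 * q3 == median**2`` (log-symmetry).
    """
    q1, q3 = iqr
    if not (0 < q1 < median < q3):
        raise ValueError(
            f"need 0 < q1 < median < q3, got median={median}, iqr={iqr}"
        )
    return math.log(median), math.log(q3 / q1) / (2 * _Z75)


@dataclass
class MetricDistributionSpec:
    """Target distribution of one metric in one group, plus derived params."""

    metric: str
    group: str  # stratum label, e.g. "benign", "sln_met", "mln_met"
    target_median: float
    target_iqr: tuple[float, float]
    family: str = "lognormal"
    location: float | None = None
    scale: float | None = None

    def calibrate(self) -> "MetricDistributionSpec":
        if self.family == "lognormal":
            self.location, self.scale = calibrate_lognormal(
                self.target_median, self.target_iqr
            )
        elif self.family == "truncated_normal":
            q1, q3 = self.target_iqr
            if not (0 < q1 < self.target_median < q3):
                raise ValueError(
                    f"need 0 < q1 < median < q3 for {self.metric}/{self.group}"
                )
            self.location = self.target_median
            self.scale = (q3 - q1) / (2 * _Z75)
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.scale > 0:
            raise ValueError(f"calibration produced non-positive scale: {self}")
        return self

    @property
    def calibration_residual(self) -> float:
        """Relative log-asymmetry of the target IQR about the median; zero
        iff the calibrated distribution reproduces the IQR exactly."""
        q1, q3 = self.target_iqr
        return abs(math.log(q1 * q3) - 2 * math.log(self.target_median))

    def _frozen(self):
        if self.location is None:
            self.calibrate()
        if self.family == "lognormal":
            return stats.lognorm(s=self.scale, scale=math.exp(self.location))
        a = (0.0 - self.location) / self.scale
        return stats.truncnorm(a, np.inf, loc=self.location, scale=self.scale)

    def cdf(self, t):
        return self._frozen().cdf(t)

    def ppf(self, q):
        return self._frozen().ppf(q)

    def sample(self, rng: np.random.Generator, n: int, patient_z=0.0) -> np.ndarray:
        """Draw n values, optionally shifted by a shared patient effect.

        ``patient_z`` is the patient's standard-normal effect already scaled
        by ``sqrt(f)``; the residual draw uses ``sqrt(1-f)`` of the scale so
        the marginal distribution stays at the calibrated target (lognormal
        family; for the truncated-normal family the effect acts additively
        on the same decomposition).
        """
        if self.location is None:
            self.calibrate()
        eps = rng.standard_normal(n)
        if self.family == "lognormal":
            return np.exp(self.location + self.scale * (patient_z + eps * self._resid))
        vals = self.location + self.scale * (patient_z + eps * self._resid)
        return np.maximum(vals, 1e-9)

    # residual scale multiplier sqrt(1-f); set by the generator
    _resid: float = field(default=1.0, repr=False)


_SLN_BASINS = ((Basin.INGUINAL, 0.49), (Basin.AXILLARY, 0.45), (Basin.CERVICAL, 0.06))
_MLN_BASINS = (
    (Basin.AXILLARY, 0.587),
    (Basin.MESENTERIAL, 0.267),
    (Basin.INGUINAL, 0.093),
    (Basin.CERVICAL, 0.027),
    (Basin.ILIACAL, 0.026),
)


@dataclass
class SyntheticCohortConfig:
    """Everything :func:`generate_cohort` needs, defaulting to the study
    conditions the pipeline is designed for (built by :func:`default_config`).

    ``reader2_noise_sd``/``reader2_bias`` are in the measurement's own units
    and follow the R1 - R2 sign convention, so reader 2 draws
    ``R1 - bias + N(0, sd)``. Noise SDs are calibrated from limits-of-
    agreement half-widths divided by 1.96.
    """

    n_patients_sln: int = 52
    n_patients_mln: int = 12
    # P(1), P(2), P(3) sentinel nodes per patient
    sln_nodes_per_patient: tuple[float, ...] = (0.65, 0.30, 0.05)
    mln_extra_nodes_mean: float = 5.25  # nodes per MLN patient = 1 + Poisson
    sln_metastatic_prob: float = 7.0 / 71.0
    # fraction of metastatic nodes whose ADCs are drawn from the benign
    # distribution (micrometastasis mimic)
    micromet_fraction_sln: float = 2.0 / 7.0
    micromet_fraction_mln: float = 0.0
    adc_specs: dict = field(default_factory=dict)  # (stratum, Sequence) -> spec
    muscle_specs: dict = field(default_factory=dict)  # Sequence -> spec
    sad_specs: dict = field(default_factory=dict)  # stratum -> spec
    voi_specs: dict = field(default_factory=dict)  # stratum -> spec
    roi_specs: dict = field(default_factory=dict)  # (stratum, Sequence) -> spec
    node_rads_probs: dict = field(default_factory=dict)  # stratum -> 5 probs
    intra_patient_sd_fraction: float = 0.3
    reader2_noise_sd: dict = field(default_factory=dict)
    reader2_bias: dict = field(default_factory=dict)
    family: str = "lognormal"
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.sln_nodes_per_patient) - 1.0) > 1e-9:
            raise ValueError("sln_nodes_per_patient probabilities must sum to 1")
        for stratum, probs in self.node_rads_probs.items():
            if len(probs) != 5 or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(
                    f"Node-RADS probabilities for {stratum!r} must be 5 values "
                    f"summing to 1"
                )
            if any(p < 0 for p in probs):
                raise ValueError(f"negative Node-RADS probability for {stratum!r}")
        for sd in self.reader2_noise_sd.values():
            if sd < 0:
                raise ValueError("reader-2 noise SDs must be non-negative")
        if not 0.0 <= self.intra_patient_sd_fraction <= 1.0:
            raise ValueError("intra_patient_sd_fraction must be in [0, 1]")
        if not (0 <= self.sln_metastatic_prob <= 1):
            raise ValueError("sln_metastatic_prob must be a probability")
        for spec_map in (self.adc_specs, self.roi_specs):
            for spec in spec_map.values():
                spec.calibrate()
        for spec in (
            list(self.muscle_specs.values())
            + list(self.sad_specs.values())
            + list(self.voi_specs.values())
        ):
            spec.calibrate()

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (Sequence, Basin)):
                return o.value
            return str(o)

        d = asdict(self)
        for key in ("adc_specs", "roi_specs"):
            d[key] = {f"{k[0]}/{k[1].value}": v for k, v in d[key].items()}
        d["muscle_specs"] = {k.value: v for k, v in d["muscle_specs"].items()}
        return json.dumps(d, indent=2, default=enc)


def _spec(metric, group, median, iqr, family) -> MetricDistributionSpec:
    return MetricDistributionSpec(metric, group, median, iqr, family).calibrate()


def default_config(seed: int = 0, family: str = "lognormal") -> SyntheticCohortConfig:
    """Study-condition defaults.

    Nodal and reference ADC distributions (10^-6 mm^2/s), SAD (mm),
    Node-RADS category frequencies, ROI/VOI sizes and the two-reader noise
    model are calibrated to the published per-group medians/IQRs and
    inter-reader bias/limits of agreement of the melanoma lymph-node DWI
    study this pipeline reproduces. Muscle ADC summaries are not published;
    their defaults are chosen so the implied muscle-ratio medians match the
    published ones given the nodal ADC medians, with a spread comparable to
    the benign nodal spread (see docs/methods.md).
    """
    E, R, V = Sequence.EPI, Sequence.RESOLVE, Sequence.VOL
    cfg = SyntheticCohortConfig(seed=seed, family=family)
    f = family
    cfg.adc_specs = {
        ("benign", E): _spec("adc_epi", "benign", 943, (866, 1066), f),
        ("benign", R): _spec("adc_res", "benign", 990, (858, 1111), f),
        ("benign", V): _spec("adc_vol", "benign", 1174, (998, 1421), f),
        ("sln_met", E): _spec("adc_epi", "sln_met", 695, (644, 781.5), f),
        ("sln_met", R): _spec("adc_res", "sln_met", 799, (715, 873), f),
        ("sln_met", V): _spec("adc_vol", "sln_met", 1020, (895, 1187), f),
        ("mln_met", E): _spec("adc_epi", "mln_met", 616, (566, 681), f),
        ("mln_met", R): _spec("adc_res", "mln_met", 762, (692.5, 869.5), f),
        ("mln_met", V): _spec("adc_vol", "mln_met", 771, (695, 815), f),
    }
    cfg.muscle_specs = {
        E: _spec("muscle_epi", "all", 1520, (1394, 1657), f),
        R: _spec("muscle_res", "all", 1620, (1486, 1766), f),
        V: _spec("muscle_vol", "all", 1500, (1376, 1635), f),
    }
    cfg.sad_specs = {
        "benign": _spec("sad", "benign", 5, (4, 7), f),
        "sln_met": _spec("sad", "sln_met", 7, (5.5, 7.5), f),
        "mln_met": _spec("sad", "mln_met", 9, (7.5, 15.5), f),
    }
    cfg.voi_specs = {
        "benign": _spec("voi", "benign", 380, (185, 925), f),
        "sln_met": _spec("voi", "sln_met", 250, (160, 730), f),
        "mln_met": _spec("voi", "mln_met", 480, (220, 1270), f),
    }
    cfg.roi_specs = {
        ("benign", E): _spec("roi_epi", "benign", 10, (6, 14), f),
        ("benign", R): _spec("roi_res", "benign", 9, (6, 12), f),
        ("sln_met", E): _spec("roi_epi", "sln_met", 4, (3, 6), f),
        ("sln_met", R): _spec("roi_res", "sln_met", 3, (2, 5), f),
        ("mln_met", E): _spec("roi_epi", "mln_met", 7, (4, 12), f),
        ("mln_met", R): _spec("roi_res", "mln_met", 10, (6, 17), f),
    }
    cfg.node_rads_probs = {
        "benign": (0.30, 0.35, 0.22, 0.09, 0.04),
        "sln_met": (0.35, 0.45, 0.15, 0.04, 0.01),
        "mln_met": (0.02, 0.08, 0.25, 0.35, 0.30),
    }
    # LoA half-width / 1.96 per raw measurement; R1 - R2 bias convention
    cfg.reader2_noise_sd = {
        "adc_epi": (212 + 207) / (2 * 1.96),  # ~106.9
        "adc_res": (281 + 257) / (2 * 1.96),  # ~137.2
        "sad": (3.83 + 4.67) / (2 * 1.96),  # ~2.17
        "node_rads": (1.50 + 2.29) / (2 * 1.96),  # ~0.97
        "roi": 4.5,
    }
    cfg.reader2_bias = {
        "adc_epi": 2.5,
        "adc_res": 12.3,
        "sad": -0.42,
        "node_rads": -0.40,
        "roi": 1.5,
    }
    return cfg


def recovery_config(seed: int = 0, n_per_group: int = 150) -> SyntheticCohortConfig:
    """A parameter-recovery variant of the defaults: ~n benign sentinel
    nodes (no positives, no micrometastasis mimic) and ~n confirmed
    metastatic nodes."""
    cfg = default_config(seed=seed)
    cfg.n_patients_sln = max(1, n_per_group // 2)
    cfg.sln_nodes_per_patient = (0.0, 1.0, 0.0)  # exactly two nodes each
    cfg.sln_metastatic_prob = 0.0
    cfg.micromet_fraction_sln = 0.0
    cfg.n_patients_mln = max(1, round(n_per_group / 6.25))
    return cfg


def _draw_categorical(rng, pairs):
    items = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs], dtype=float)
    probs = probs / probs.sum()
    return items[rng.choice(len(items), p=probs)]


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[LymphNodeRecord], list[ReferencePanel], pd.DataFrame]:
    """Sample a two-reader cohort; deterministic given ``config.seed``.

    Returns ``(records, panels, truth)`` conforming to the cohort-table
    schema: two records per node (readers R1 and R2 — reader 2 re-measures
    the ROI-based sequences, SAD and Node-RADS, but not the volumetric
    sequence), one reference panel per patient and reader, and a node-level
    truth table with the generating stratum.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    f = config.intra_patient_sd_fraction
    sqrt_f, resid = math.sqrt(f), math.sqrt(1.0 - f)
    for spec_map in (config.adc_specs, config.roi_specs):
        for spec in spec_map.values():
            spec._resid = resid
    for spec in (
        list(config.muscle_specs.values())
        + list(config.sad_specs.values())
        + list(config.voi_specs.values())
    ):
        spec._resid = resid

    E, R, V = Sequence.EPI, Sequence.RESOLVE, Sequence.VOL
    records: list[LymphNodeRecord] = []
    panels: list[ReferencePanel] = []
    truth_rows = []

    def one(spec, z) -> float:
        return float(spec.sample(rng, 1, patient_z=z)[0])

    def r2_value(v1: float, key: str, lo: float) -> float:
        sd = config.reader2_noise_sd.get(key, 0.0)
        bias = config.reader2_bias.get(key, 0.0)
        return max(v1 - bias + rng.normal(0.0, sd), lo)

    def make_panels(pid: str, z: float):
        contra1 = {
            seq: [one(config.adc_specs[("benign", seq)], z) for _ in range(3)]
            for seq in (E, R, V)
        }
        muscle1 = {seq: one(config.muscle_specs[seq], z) for seq in (E, R, V)}
        p1 = ReferencePanel(pid, Reader.R1, contra1, muscle1)
        key = {E: "adc_epi", R: "adc_res"}
        contra2 = {
            seq: [r2_value(v, key[seq], 1.0) for v in contra1[seq]] for seq in (E, R)
        }
        muscle2 = {seq: r2_value(muscle1[seq], key[seq], 1.0) for seq in (E, R)}
        p2 = ReferencePanel(pid, Reader.R2, contra2, muscle2)
        panels.extend([p1, p2])

    def make_node(pid, nid, group, basin, truth, stratum, z):
        adc1 = {seq: one(config.adc_specs[(stratum, seq)], z) for seq in (E, R, V)}
        roi1 = {
            seq: max(2, round(one(config.roi_specs[(stratum, seq)], z)))
            for seq in (E, R)
        }
        # the micromet mimic draws benign-like ADCs but keeps the metastatic
        # morphology stratum of its cohort group
        if truth is TruthStatus.METASTATIC:
            morph_stratum = "sln_met" if group is CohortGroup.SLN else "mln_met"
        else:
            morph_stratum = "benign"
        sad1 = round(one(config.sad_specs[morph_stratum], z), 1)
        voi1 = round(one(config.voi_specs[morph_stratum], z), 1)
        nr_probs = config.node_rads_probs[morph_stratum]
        nr1 = int(rng.choice(5, p=np.asarray(nr_probs) / sum(nr_probs))) + 1
        records.append(
            LymphNodeRecord(
                pid, nid, group, basin, truth, Reader.R1,
                adc=dict(adc1), roi_voxels=roi1, voi_mm3=voi1,
                sad_mm=sad1, node_rads=nr1,
            )
        )
        adc2 = {
            E: r2_value(adc1[E], "adc_epi", 1.0),
            R: r2_value(adc1[R], "adc_res", 1.0),
        }
        roi2 = {
            seq: max(2, round(r2_value(roi1[seq], "roi", 2.0))) for seq in (E, R)
        }
        sad2 = round(r2_value(sad1, "sad", 0.5), 1)
        nr2 = int(np.clip(round(r2_value(nr1, "node_rads", 1.0)), 1, 5))
        records.append(
            LymphNodeRecord(
                pid, nid, group, basin, truth, Reader.R2,
                adc=adc2, roi_voxels=roi2, voi_mm3=None,
                sad_mm=sad2, node_rads=nr2,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "node_id": nid,
                "cohort_group": group.value,
                "truth_status": truth.value,
                "adc_stratum": stratum,
            }
        )

    for i in range(config.n_patients_sln):
        pid = f"S{i + 1:03d}"
        z = sqrt_f * rng.standard_normal()
        make_panels(pid, z)
        n_nodes = int(rng.choice([1, 2, 3], p=config.sln_nodes_per_patient))
        basin = _draw_categorical(rng, _SLN_BASINS)
        for j in range(n_nodes):
            met = rng.random() < config.sln_metastatic_prob
            truth = TruthStatus.METASTATIC if met else TruthStatus.BENIGN
            stratum = "benign"
            if met:
                micro = rng.random() < config.micromet_fraction_sln
                stratum = "benign" if micro else "sln_met"
            make_node(pid, f"n{j + 1}", CohortGroup.SLN, basin, truth, stratum, z)

    for i in range(config.n_patients_mln):
        pid = f"M{i + 1:03d}"
        z = sqrt_f * rng.standard_normal()
        make_panels(pid, z)
        n_nodes = 1 + int(rng.poisson(config.mln_extra_nodes_mean))
        basin = _draw_categorical(rng, _MLN_BASINS)
        for j in range(n_nodes):
            micro = rng.random() < config.micromet_fraction_mln
            stratum = "benign" if micro else "mln_met"
            make_node(
                pid, f"n{j + 1}", CohortGroup.MLN, basin,
                TruthStatus.METASTATIC, stratum, z,
            )

    return records, panels, pd.DataFrame(truth_rows)


def reference_structure_cohort() -> list[LymphNodeRecord]:
    """A deterministic minimal cohort reproducing the study's set structure.

    Sentinel cohort: 52 patients contributing 76 sentinel nodes — 45
    patients with only benign nodes (64 nodes), 4 patients with one
    metastatic node each, and 3 patients with one metastatic plus five
    benign nodes between them (those five are the nodes the sentinel-set
    rule excludes). Advanced cohort: 12 patients contributing 75 confirmed
    metastatic nodes. Reader 1 only; measurement values are simple
    deterministic placeholders — this cohort exercises set construction,
    not distributional behaviour.
    """
    records: list[LymphNodeRecord] = []

    def node(pid, nid, group, truth, adc):
        records.append(
            LymphNodeRecord(
                pid, nid, group, Basin.INGUINAL, truth, Reader.R1,
                adc={Sequence.EPI: float(adc)}, sad_mm=6.0, node_rads=2,
            )
        )

    k = 0
    for i in range(1, 46):  # 19 patients x 2 nodes + 26 x 1 node = 64 benign
        for j in range(2 if i <= 19 else 1):
            node(f"S{i:03d}", f"n{j + 1}", CohortGroup.SLN,
                 TruthStatus.BENIGN, 900 + (k % 40))
            k += 1
    for i in range(46, 50):  # 4 patients with only a positive sentinel node
        node(f"S{i:03d}", "n1", CohortGroup.SLN, TruthStatus.METASTATIC, 650 + i)
    bound_benign = (2, 2, 1)  # the five nodes excluded by the sentinel rule
    for i, extra in zip(range(50, 53), bound_benign):
        node(f"S{i:03d}", "n1", CohortGroup.SLN, TruthStatus.METASTATIC, 650 + i)
        for j in range(extra):
            node(f"S{i:03d}", f"n{j + 2}", CohortGroup.SLN,
                 TruthStatus.BENIGN, 905 + i + j)
    mln_nodes = (7, 7, 7, 6, 6, 6, 6, 6, 6, 6, 6, 6)  # 75 nodes
    for i, n in enumerate(mln_nodes, start=1):
        for j in range(n):
            node(f"M{i:03d}", f"n{j + 1}", CohortGroup.MLN,
                 TruthStatus.METASTATIC, 600 + i + j)
    return records


# ---------------------------------------------------------------------------
# generator-truth cut-offs
# ---------------------------------------------------------------------------


@dataclass
class ImpliedCutoff:
    cutoff: float
    youden_j: float
    degenerate: bool = False
    boundary: bool = False


def implied_optimal_cutoff(
    spec_benign: MetricDistributionSpec,
    spec_metastatic: MetricDistributionSpec,
    orientation: Orientation = Orientation.LOWER_IS_POSITIVE,
) -> ImpliedCutoff:
    """Population-optimal Youden cut-off for a calibrated spec pair.

    Maximizes J(t) = sensitivity(t) + specificity(t) - 1 using the closed-
    form distribution functions. Identical specs are flagged degenerate
    (J = 0); essentially non-overlapping supports yield J -> 1 with a
    boundary flag.
    """
    fb, fm = spec_benign._frozen(), spec_metastatic._frozen()

    if orientation is Orientation.LOWER_IS_POSITIVE:
        def negj(t):
            return -(fm.cdf(t) - fb.cdf(t))
    else:
        def negj(t):
            return -(fb.cdf(t) - fm.cdf(t))

    lo = min(fb.ppf(1e-9), fm.ppf(1e-9))
    hi = max(fb.ppf(1 - 1e-9), fm.ppf(1 - 1e-9))
    grid = np.linspace(lo, hi, 2001)
    jg = -np.array([negj(t) for t in grid])
    i = int(np.argmax(jg))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(negj, bounds=(a, b), method="bounded")
    cutoff, j = float(res.x), float(-res.fun)
    if j < 1e-9:
        return ImpliedCutoff(cutoff=cutoff, youden_j=0.0, degenerate=True)
    if j > 1 - 1e-9:
        return ImpliedCutoff(cutoff=cutoff, youden_j=j, boundary=True)
    return ImpliedCutoff(cutoff=cutoff, youden_j=j)


def implied_ratio_spec(
    target_spec: MetricDistributionSpec,
    reference_spec: MetricDistributionSpec,
    intra_patient_sd_fraction: float,
    metric: str = "ratio",
) -> MetricDistributionSpec:
    """Exact lognormal law of target/reference under the shared patient
    effect (both specs must be lognormal).

    In log space the ratio is normal with location ``mu_t - mu_r`` and
    variance ``f*(s_t - s_r)^2 + (1-f)*(s_t^2 + s_r^2)``: the patient effect
    enters both numerator and denominator and largely cancels.
    """
    if target_spec.family != "lognormal" or reference_spec.family != "lognormal":
        raise ValueError("implied ratio law is available for lognormal specs only")
    for s in (target_spec, reference_spec):
        if s.location is None:
            s.calibrate()
    f = intra_patient_sd_fraction
    loc = target_spec.location - reference_spec.location
    var = (
        f * (target_spec.scale - reference_spec.scale) ** 2
        + (1 - f) * (target_spec.scale**2 + reference_spec.scale**2)
    )
    scale = math.sqrt(var)
    out = MetricDistributionSpec(
        metric=metric,
        group=target_spec.group,
        target_median=math.exp(loc),
        target_iqr=(math.exp(loc - _Z75 * scale), math.exp(loc + _Z75 * scale)),
        family="lognormal",
        location=loc,
        scale=scale,
    )
    return out
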