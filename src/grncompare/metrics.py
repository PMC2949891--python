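"""Verification and validation measures for reverse-engineered models.

* ``p_fit`` — 1 / (1 + E) with E the mean squared deviation between an
  observed and a predicted dataset; 1 is perfect accordance.  ``P_ver``
  applies it to the training data (verification), ``P_val`` to unseen
  data generated under perturbed network input (validation);
  ``dP_fit = P_val - P_ver`` summarizes the generalization drop.
* ``p_inf`` — inferential power 0.5 * (1 + r) with r the Pearson
  correlation between the reference and recovered free-parameter
  vectors in canonical order; only defined within a method.
* ``q_com`` — qualitative presence/absence of designed network
  features (uniform degradation, constant signal propagation,
  asymmetric branching/co-regulation, feedback loops) with fixed
  thresholds.
* ``relative_difference`` — squared relative deviation score used for
  comparisons on biological (switch-on/off) data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .codec import NetworkCodec
from .models import GRNModel
from .simulate import (IntegrationSettings, TimeSeriesSet, Trajectory,
                       integrate, perturb_input)

#: Degradation-rate window for the uniform-degradation feature.
UNIFORM_DEGRADATION_BAND = (0.2, 0.4)
#: Max/min signal ratio below which propagation counts as constant.
CONSTANT_PROPAGATION_RATIO = 2.0
#: Relative signal difference above which branching/co-regulation
#: counts as asymmetric.
ASYMMETRY_THRESHOLD = 0.2


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (a zero-variance vector)."""


def _stack(data: TimeSeriesSet) -> np.ndarray:
    return np.concatenate([tr.x for tr in data.trajectories], axis=0)


def p_fit(observed: TimeSeriesSet, predicted: TimeSeriesSet) -> float:
    """Data-fitting predictive power 1 / (1 + E), in (0, 1].

    E is the squared deviation averaged over all sampling points and
    genes; multiple trajectories are pooled into one average.
    """
    if len(observed.trajectories) != len(predicted.trajectories):
        raise ValueError("trajectory counts differ")
    obs = _stack(observed)
    pred = _stack(predicted)
    if obs.shape != pred.shape:
        raise ValueError(f"shape mismatch {obs.shape} vs {pred.shape}")
    err = float(np.mean((obs - pred) ** 2))
    return 1.0 / (1.0 + err)


def p_inf(w_ref: np.ndarray, w_hat: np.ndarray) -> float:
    """Inferential power 0.5 * (1 + pearson(w_ref, w_hat)), in [0, 1]."""
    w_ref = np.asarray(w_ref, dtype=float)
    w_hat = np.asarray(w_hat, dtype=float)
    if w_ref.shape != w_hat.shape or w_ref.ndim != 1 or len(w_ref) < 2:
        raise ValueError("parameter vectors must be equal-length, >= 2")
    if np.ptp(w_ref) == 0 or np.ptp(w_hat) == 0:
        raise UndefinedCorrelationError(
            "Pearson correlation undefined for a constant vector"
        )
    r = stats.pearsonr(w_ref, w_hat).statistic
    return 0.5 * (1.0 + r)


def p_inf_models(reference: GRNModel, inferred: GRNModel) -> float:
    """P_inf between two same-method models' canonical free parameters."""
    if reference.method != inferred.method:
        raise ValueError(
            "P_inf is only defined within a method; use q_com for "
            "cross-method comparisons"
        )
    codec = NetworkCodec(reference.method, reference.topology)
    return p_inf(codec.encode(reference), codec.encode(inferred))


def relative_difference(observed: TimeSeriesSet,
                        predicted: TimeSeriesSet) -> float:
    """Sum of squared relative deviations ((X - Xhat) / X)^2."""
    obs = _stack(observed)
    pred = _stack(predicted)
    if obs.shape != pred.shape:
        raise ValueError(f"shape mismatch {obs.shape} vs {pred.shape}")
    zero = obs == 0
    if np.any(zero):
        t, k = np.argwhere(zero)[0]
        raise ZeroDivisionError(
            f"observed value is zero at point {t}, gene {k + 1}"
        )
    return float(np.sum(((obs - pred) / obs) ** 2))


def classify_pfit(value: float) -> str:
    """Narrative quality band of a data-fitting score."""
    if value < 0.9:
        return "very poor"
    if value < 0.95:
        return "poor"
    if value < 0.99:
        return "same range, patterns may differ"
    if value < 0.999:
        return "converging"
    return "highly accurate"


# ---------------------------------------------------------------------------
# Verification and validation


def _simulate_like(model: GRNModel, data: TimeSeriesSet,
                   settings: IntegrationSettings | None = None
                   ) -> TimeSeriesSet:
    """Simulate ``model`` from each trajectory's initial state on its grid."""
    out = []
    for tr in data.trajectories:
        grid = tr.t
        s = IntegrationSettings(
            t_end=float(grid[-1]), n_points=len(grid),
            rtol=(settings.rtol if settings else 1e-6),
            atol=(settings.atol if settings else 1e-8),
            blowup=(settings.blowup if settings else 1e6))
        sim = integrate(model, tr.x[0], s, label=tr.label)
        if not sim.success:
            # worst-case sentinel: a flat zero prediction
            sim = Trajectory(tr.label, grid, np.zeros_like(tr.x),
                             success=False, message=sim.message)
        out.append(sim)
    return TimeSeriesSet(out, {"simulated_from": "initial states"})


def verify(model: GRNModel, training: TimeSeriesSet,
           settings: IntegrationSettings | None = None) -> float:
    """P_ver: reproduce the training data from its initial states."""
    predicted = _simulate_like(model, training, settings)
    return p_fit(training, predicted)


@dataclass
class ValidationResult:
    p_val: float
    per_condition: dict[str, float]
    flagged: bool = False


def validate(inferred: GRNModel, reference: GRNModel,
             training: TimeSeriesSet,
             settings: IntegrationSettings | None = None
             ) -> ValidationResult:
    """P_val: predictive power under perturbed network input.

    Both models receive the same two input perturbations (the input
    gene's degradation constant set to 0.1 and 0.5); the perturbed
    reference generates the unseen data, the perturbed inferred model
    predicts it.  P_val is the mean of the two condition scores.
    """
    if inferred.n_genes != reference.n_genes:
        raise ValueError("models differ in size")
    ref_inc, ref_dec = perturb_input(reference)
    inf_inc, inf_dec = perturb_input(inferred)
    per: dict[str, float] = {}
    flagged = False
    for name, ref_m, inf_m in (("increase (k1=0.1)", ref_inc, inf_inc),
                               ("decrease (k1=0.5)", ref_dec, inf_dec)):
        unseen = _simulate_like(ref_m, training, settings)
        predicted = _simulate_like(inf_m, training, settings)
        flagged = flagged or not (unseen.all_success
                                  and predicted.all_success)
        per[name] = p_fit(unseen, predicted)
    return ValidationResult(p_val=float(np.mean(list(per.values()))),
                            per_condition=per, flagged=flagged)


# ---------------------------------------------------------------------------
# Qualitative comparison of network features


def _signal_strengths(model: GRNModel) -> dict[tuple[int, int], float]:
    """Signed interaction strength per (source, target) edge.

    ANN: connection weight w; SS: production kinetic order g; GRLOT:
    Hill exponent n, negated for inhibitor-role regulators.
    """
    out: dict[tuple[int, int], float] = {}
    if model.method == "ANN":
        for e in model.topology.edges:
            out[(e.source, e.target)] = float(
                model.params.w[e.target - 1, e.source - 1])
    elif model.method == "SS":
        for e in model.topology.edges:
            out[(e.source, e.target)] = float(
                model.params.g[e.target - 1, e.source - 1])
    else:
        for target, regs in model.params.regulators.items():
            for r in regs:
                sgn = 1.0 if r.role == "activator" else -1.0
                out[(r.source, target)] = sgn * float(r.n)
    return out


def _asymmetric(a: float, b: float) -> bool:
    m = max(abs(a), abs(b))
    if m == 0:
        return False
    return abs(abs(a) - abs(b)) / m > ASYMMETRY_THRESHOLD


def qcom_features(model: GRNModel, case_id: str) -> dict[str, bool]:
    """Presence/absence of the case's designed network features.

    Case A: uniform degradation, constant signal propagation.
    Case B: uniform degradation, asymmetric signal branching
    (X2 -> X3 vs X2 -> X4), asymmetric co-regulation (X3 -> X5 vs
    X4 -> X5).  Case C: case B's branching features plus positive
    feedback (X3 -> X2) and negative feedback (X5 -> X2).
    """
    if case_id not in ("A", "B", "C"):
        raise ValueError(f"qualitative features defined for cases A-C, "
                         f"got {case_id!r}")
    lo, hi = UNIFORM_DEGRADATION_BAND
    rates = model.degradation_rates()
    feats: dict[str, bool] = {
        "uniform_degradation": bool(np.all((rates >= lo) & (rates <= hi)))
    }
    s = _signal_strengths(model)
    if case_id == "A":
        mags = [abs(v) for v in s.values()]
        feats["constant_signal_propagation"] = (
            len(mags) > 0 and min(mags) > 0
            and max(mags) / min(mags) < CONSTANT_PROPAGATION_RATIO)
    else:
        feats["asymmetric_signal_branching"] = _asymmetric(
            s.get((2, 3), 0.0), s.get((2, 4), 0.0))
        feats["asymmetric_coregulation"] = _asymmetric(
            s.get((3, 5), 0.0), s.get((4, 5), 0.0))
        if case_id == "C":
            feats["positive_feedback"] = s.get((3, 2), 0.0) > 0
            feats["negative_feedback"] = s.get((5, 2), 0.0) < 0
    return feats


# ---------------------------------------------------------------------------
# Report container


@dataclass
class EvaluationReport:
    """All measures for one (reference, inferred) model pair."""

    case_id: str
    gen_method: str
    inf_method: str
    density: str
    p_ver: float
    p_val: float
    per_condition: dict[str, float] = field(default_factory=dict)
    p_inf: float | None = None          # within-method only
    q_com: dict[str, bool] = field(default_factory=dict)
    flagged: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.p_inf is not None and self.gen_method != self.inf_method:
            raise ValueError(
                "P_inf is only populated for within-method pairs"
            )

    @property
    def delta_p_fit(self) -> float:
        return self.p_val - self.p_ver

    def to_dict(self) -> dict:
        return {
            "case": self.case_id,
            "gen_method": self.gen_method,
            "inf_method": self.inf_method,
            "density": self.density,
            "P_inf": self.p_inf,
            "P_ver": self.p_ver,
            "P_val": self.p_val,
            "dP_fit": self.delta_p_fit,
            "per_condition": self.per_condition,
            "Q_com": self.q_com,
            "flagged": self.flagged,
            "seed": self.seed,
        }


def evaluate_pair(inferred: GRNModel, reference: GRNModel,
                  training: TimeSeriesSet, case_id: str,
                  density: str, seed: int | None = None,
                  settings: IntegrationSettings | None = None
                  ) -> EvaluationReport:
    """Compute P_ver, P_val, dP_fit, P_inf (within-method) and Q_com."""
    ver = verify(inferred, training, settings)
    val = validate(inferred, reference, training, settings)
    inf_val = None
    if inferred.method == reference.method:
        inf_val = p_inf_models(reference, inferred)
    q = (qcom_features(inferred, case_id)
         if case_id in ("A", "B", "C") else {})
    return EvaluationReport(
        case_id=case_id, gen_method=reference.method,
        inf_method=inferred.method, density=density,
        p_ver=ver, p_val=val.p_val, per_condition=val.per_condition,
        p_inf=inf_val, q_com=q, flagged=val.flagged, seed=seed)
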