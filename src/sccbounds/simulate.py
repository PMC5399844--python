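"""Synthetic cohorts from a fully specified sufficient-component-cause model.

The generator exists so the bounds can be validated against a known truth:
a model fixes the completion probability of every causal-pie class, the
analytic profile risks follow, and the bounds computed from those risks
must bracket the true class completion risks.

Model.  For exposures with ``L1`` and ``L2`` levels there are
``(L1+1) x (L2+1)`` causal-pie classes, indexed here with 0 standing for
the null label ``*`` (the factor is not a component of the pie): one
all-unknown class ``(*, *)``, ``L1 + L2`` main-effect classes, and
``L1 x L2`` interaction classes.  Each class carries a *peril* — the
cumulative hazard of its unknown complement components arriving during the
study window — so its completion probability is ``1 - exp(-peril)``.
Arrivals are independent across classes by default (the simplest law
compatible with the no-redundancy assumption: in continuous time,
simultaneous arrivals have probability zero), and perils then add:

    Risk^{profile=i,j} = 1 - exp(-(q[*,*] + q[i,*] + q[*,j] + q[i,j]))

since a subject with profile ``(i, j)`` is diseased iff any of the four
classes relevant to that profile completes.  The true targets of the
bounds are then closed-form::

    specific  Risk_class=i,j = 1 - exp(-q[i,j])
    global    Risk_class=int = 1 - exp(-sum of all interaction perils)

An optional equicorrelated Gaussian copula over the latent arrival
indicators (``dependence`` in [0, 1)) relaxes independence while
keeping the no-redundancy assumption intact; the closed forms above assume
independence, so the analytic accessors refuse a dependent model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.stats import norm

from .types import CohortTable, Level, RiskMatrix

__all__ = [
    "SCCModel",
    "profile_risk_analytic",
    "profile_risk_matrix",
    "true_interaction_risks",
    "simulate_cohort",
    "read_model_config",
    "write_model_config",
]


@dataclass(frozen=True)
class SCCModel:
    """A sufficient-component-cause data-generating process.

    Parameters
    ----------
    class_perils
        ``(L1+1) x (L2+1)`` array of non-negative cumulative hazards; row
        and column 0 hold the null label ``*``, so ``class_perils[0, 0]``
        is the all-unknown class, ``class_perils[i, 0]`` (``i >= 1``) the
        ``X1``-only main-effect classes, and ``class_perils[i, j]`` with
        ``i, j >= 1`` the interaction classes.
    exposure_distribution
        ``L1 x L2`` probabilities of the exposure profiles (sums to 1).
    cohort_size
        Number of subjects drawn per simulated cohort.
    dependence
        Latent equicorrelation of class arrivals (0 = independent).
    """

    class_perils: np.ndarray
    exposure_distribution: np.ndarray
    cohort_size: int
    level_labels_1: tuple[str, ...] = None  # type: ignore[assignment]
    level_labels_2: tuple[str, ...] = None  # type: ignore[assignment]
    dependence: float = 0.0

    def __post_init__(self) -> None:
        q = np.asarray(self.class_perils, float)
        p = np.asarray(self.exposure_distribution, float)
        if q.ndim != 2 or q.shape[0] < 3 or q.shape[1] < 3:
            raise ValueError(
                "class_perils must be (L1+1) x (L2+1) with L1, L2 >= 2, "
                f"got shape {q.shape}"
            )
        if not np.all(np.isfinite(q)) or np.any(q < 0):
            raise ValueError("perils must be non-negative and finite")
        if p.shape != (q.shape[0] - 1, q.shape[1] - 1):
            raise ValueError(
                f"exposure_distribution shape {p.shape} does not match "
                f"L1 x L2 = {(q.shape[0] - 1, q.shape[1] - 1)}"
            )
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("exposure distribution must be non-negative and sum to 1")
        if self.cohort_size < 0:
            raise ValueError("cohort_size must be non-negative")
        if not 0.0 <= self.dependence < 1.0:
            raise ValueError("dependence must lie in [0, 1)")
        object.__setattr__(self, "class_perils", q)
        object.__setattr__(self, "exposure_distribution", p)
        from .types import _as_labels  # shared validation

        object.__setattr__(
            self, "level_labels_1", _as_labels(self.level_labels_1, p.shape[0], 1)
        )
        object.__setattr__(
            self, "level_labels_2", _as_labels(self.level_labels_2, p.shape[1], 2)
        )

    @property
    def L1(self) -> int:
        return self.class_perils.shape[0] - 1

    @property
    def L2(self) -> int:
        return self.class_perils.shape[1] - 1

    def completion_probabilities(self) -> np.ndarray:
        """Per-class ``Pr(U = 1) = 1 - exp(-peril)``, same layout as perils."""
        return -np.expm1(-self.class_perils)

    def _require_independent(self, what: str) -> None:
        if self.dependence != 0.0:
            raise ValueError(
                f"{what} is closed-form only under independent class "
                "arrivals (dependence = 0)"
            )


def profile_risk_analytic(model: SCCModel, i: Level, j: Level) -> float:
    """Exact cumulative disease risk of profile ``(i, j)`` under the model."""
    from .types import _resolve_level

    a = _resolve_level(i, model.level_labels_1, 1)
    b = _resolve_level(j, model.level_labels_2, 2)
    model._require_independent("profile risk")
    q = model.class_perils
    total = q[0, 0] + q[a + 1, 0] + q[0, b + 1] + q[a + 1, b + 1]
    return float(-np.expm1(-total))


def profile_risk_matrix(model: SCCModel) -> RiskMatrix:
    """All analytic profile risks as a :class:`RiskMatrix`."""
    model._require_independent("profile risk")
    q = model.class_perils
    tot = q[0:1, 0:1] + q[1:, 0:1] + q[0:1, 1:] + q[1:, 1:]
    return RiskMatrix(-np.expm1(-tot), model.level_labels_1, model.level_labels_2)


def true_interaction_risks(model: SCCModel) -> tuple[np.ndarray, float]:
    """True completion risks the bounds are trying to trap.

    Returns the ``L1 x L2`` matrix of specific interaction-class completion
    risks ``1 - exp(-q_ij)`` and the global completion risk
    ``1 - exp(-sum q_ij)`` (union over all interaction classes, exact under
    independent arrivals).
    """
    model._require_independent("interaction completion risk")
    q_int = model.class_perils[1:, 1:]
    specific = -np.expm1(-q_int)
    global_ = float(-np.expm1(-q_int.sum()))
    return specific, global_


def simulate_cohort(model: SCCModel, seed: Optional[int] = None) -> CohortTable:
    """Draw one cohort: profiles from the exposure distribution, then
    disease status per subject.

    Under independence (the default) disease is Bernoulli with the analytic
    profile risk.  With ``dependence != 0`` each subject's four relevant
    class indicators are thresholded correlated Gaussians (a copula over
    arrival indicators) and disease is their union.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    p = model.exposure_distribution.ravel()
    totals = rng.multinomial(model.cohort_size, p).reshape(model.L1, model.L2)
    cases = np.zeros_like(totals)
    probs = model.completion_probabilities()
    for a in range(model.L1):
        for b in range(model.L2):
            n = int(totals[a, b])
            if n == 0:
                continue
            if model.dependence == 0.0:
                q = model.class_perils
                risk = -np.expm1(
                    -(q[0, 0] + q[a + 1, 0] + q[0, b + 1] + q[a + 1, b + 1])
                )
                cases[a, b] = rng.binomial(n, risk)
            else:
                pr = np.array(
                    [probs[0, 0], probs[a + 1, 0], probs[0, b + 1], probs[a + 1, b + 1]]
                )
                rho = model.dependence
                # equicorrelated normals via a shared factor
                shared = rng.standard_normal((n, 1))
                eps = rng.standard_normal((n, 4))
                z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
                u = z < norm.ppf(pr)
                cases[a, b] = int(np.any(u, axis=1).sum())
    return CohortTable(cases, totals, model.level_labels_1, model.level_labels_2)


# ---------------------------------------------------------------------------
# config file round-trip (key-value YAML)

def read_model_config(path) -> SCCModel:
    """Load an :class:`SCCModel` from a YAML mapping.

    Keys: ``class_perils`` (nested lists, (L1+1) x (L2+1)),
    ``exposure_distribution`` (L1 x L2), ``cohort_size``, optional
    ``levels_1`` / ``levels_2`` label lists and ``dependence``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    try:
        return SCCModel(
            class_perils=np.asarray(cfg["class_perils"], float),
            exposure_distribution=np.asarray(cfg["exposure_distribution"], float),
            cohort_size=int(cfg["cohort_size"]),
            level_labels_1=tuple(cfg["levels_1"]) if "levels_1" in cfg else None,
            level_labels_2=tuple(cfg["levels_2"]) if "levels_2" in cfg else None,
            dependence=float(cfg.get("dependence", 0.0)),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing required key {exc}") from None


def write_model_config(model: SCCModel, path) -> None:
    cfg = {
        "class_perils": model.class_perils.tolist(),
        "exposure_distribution": model.exposure_distribution.tolist(),
        "cohort_size": model.cohort_size,
        "levels_1": list(model.level_labels_1),
        "levels_2": list(model.level_labels_2),
        "dependence": model.dependence,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
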