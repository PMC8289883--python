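"""Placing separately calibrated test forms on a common scale.

All methods here are translation links: under the Rasch model a linking
transformation can only shift the logit scale, so a single additive constant
per adjacent form pair carries the linking information.  The first time point
t1 defines the reference scale; forms t2..t4 are linked sequentially (t2 to
t1, t3 to the linked t2, and so on), because adjacent pairs share different
anchor sets.

Methods:

``mean_mean``
    v = M(delta_B,anchors) - M(delta_A,anchors): the difference of the anchor
    difficulty means between the reference form B and the form A being linked.
``weighted_mean_mean``
    as mean/mean but with each side's anchor mean weighted by the inverse
    squared standard errors of the difficulty estimates; identical to
    mean/mean when SEs are equal within each form.
``fpc`` (fixed parameter calibration)
    each new form is calibrated with its anchors *fixed* at the previous
    form's already-linked estimates while the latent mean and variance are
    estimated, so the common-scale moments are read off directly and no
    explicit constant is formed.
``concurrent``
    one joint calibration of all forms with equality-constrained anchors
    (see :func:`ralisim.estimation.fit_concurrent`).

Common-scale moments: for the separate methods the latent mean at time t is
the chained constant V_t (each free calibration has its mean identified at 0)
and the variance is the form's own estimate, which no translation can alter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import CalibrationResult, CalibrationSpec, fit_concurrent, fit_mml_em
from .simulate import ConfigurationError, ResponseMatrix

SEPARATE_METHODS = ("fpc", "mean_mean", "weighted_mean_mean")
METHODS = SEPARATE_METHODS + ("concurrent",)


# ---------------------------------------------------------------------------
# linking constants
# ---------------------------------------------------------------------------

def mean_mean_constant(anchors_A: Sequence[float], anchors_B: Sequence[float]) -> float:
    """Mean/mean linking constant v = mean(delta_B) - mean(delta_A).

    Form A is being linked onto reference form B; matched anchors only.
    """
    a = np.asarray(anchors_A, dtype=float)
    b = np.asarray(anchors_B, dtype=float)
    if a.size == 0 or a.size != b.size:
        raise ValueError("anchor lists must be non-empty and matched")
    return float(b.mean() - a.mean())


def weighted_mean_mean_constant(
    anchors_A: Sequence[float],
    se_A: Sequence[float],
    anchors_B: Sequence[float],
    se_B: Sequence[float],
    weighting: str = "per_side",
) -> float:
    """Precision-weighted linking constant v'.

    Two weighting conventions are provided; both reduce to the plain
    mean/mean constant when standard errors are constant within each form.

    ``per_side``
        v' = sum(delta_B * SE_B^-2)/sum(SE_B^-2)
             - sum(delta_A * SE_A^-2)/sum(SE_A^-2),
        i.e. each side's anchor mean is precision-weighted and normalized
        separately.  Caution: when anchor precision correlates with
        difficulty - which an anchor block targeted *between* two shifted
        ability distributions guarantees, with opposite signs on the two
        sides - the two weighted means shift in opposite directions and the
        constant is systematically attenuated.
    ``pooled_difference``
        the inverse-variance weighted mean of the per-anchor differences,
        v' = sum(w_l (delta_Bl - delta_Al)) / sum(w_l) with
        w_l = 1/(SE_Al^2 + SE_Bl^2).  Each anchor contributes its own
        difference, so precision-difficulty correlation cannot bias the
        constant; this is the convention the study pipeline uses.
    """
    a, sa = np.asarray(anchors_A, float), np.asarray(se_A, float)
    b, sb = np.asarray(anchors_B, float), np.asarray(se_B, float)
    if a.size == 0 or not (a.size == sa.size == b.size == sb.size):
        raise ValueError("anchor/SE lists must be non-empty and matched")
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise ValueError("all anchor SEs must be positive")
    if weighting == "per_side":
        wa, wb = sa**-2, sb**-2
        return float((b @ wb) / wb.sum() - (a @ wa) / wa.sum())
    if weighting == "pooled_difference":
        w = 1.0 / (sa**2 + sb**2)
        return float(((b - a) @ w) / w.sum())
    raise ValueError(f"unknown weighting {weighting!r}")


def apply_link(calibration: CalibrationResult, v: float) -> CalibrationResult:
    """Shift a calibration onto the reference scale: delta* = delta + v.

    The latent mean shifts by v; the variance is translation invariant.
    """
    if not np.isfinite(v):
        raise ValueError("linking constant must be finite")
    return CalibrationResult(
        difficulties={k: d + v for k, d in calibration.difficulties.items()},
        se=dict(calibration.se),
        fixed=calibration.fixed,
        mu=(calibration.mu + v) if calibration.mu is not None else None,
        sigma2=calibration.sigma2,
        loglik=calibration.loglik,
        n_iter=calibration.n_iter,
        converged=calibration.converged,
        mode=calibration.mode,
        excluded=calibration.excluded,
        loglik_path=calibration.loglik_path,
    )


def chain_links(constants: Sequence[float]) -> list[float]:
    """Cumulative constants V_t from per-pair constants; V_1 = 0."""
    return [0.0, *np.cumsum(np.asarray(constants, dtype=float)).tolist()]


# ---------------------------------------------------------------------------
# link results
# ---------------------------------------------------------------------------

@dataclass
class LinkResult:
    """Common-scale summary of one linking run over all time points."""

    method: str
    timepoints: list[int]
    mu: dict[int, float]  # common-scale latent mean per time point
    sigma2: dict[int, float]
    per_pair_constants: dict[int, float] = field(default_factory=dict)
    cumulative_constants: dict[int, float] = field(default_factory=dict)
    anchor_ids: dict[int, frozenset[str]] = field(default_factory=dict)
    converged_by_form: dict[int, bool] = field(default_factory=dict)
    linked_difficulties: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return all(self.converged_by_form.values())

    def moments_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "timepoint": self.timepoints,
                "v": [self.per_pair_constants.get(t - 1, np.nan) for t in self.timepoints],
                "V": [self.cumulative_constants.get(t, np.nan) for t in self.timepoints],
                "mu_hat": [self.mu[t] for t in self.timepoints],
                "sigma2_hat": [self.sigma2[t] for t in self.timepoints],
                "converged": [self.converged_by_form.get(t, True) for t in self.timepoints],
            }
        )

    def to_json(self, path=None) -> str:
        payload = {
            "method": self.method,
            "timepoints": self.timepoints,
            "mu": {str(t): v for t, v in self.mu.items()},
            "sigma2": {str(t): v for t, v in self.sigma2.items()},
            "per_pair_constants": {str(p): v for p, v in self.per_pair_constants.items()},
            "cumulative_constants": {str(t): v for t, v in self.cumulative_constants.items()},
            "anchor_ids": {str(p): sorted(s) for p, s in self.anchor_ids.items()},
            "converged_by_form": {str(t): bool(c) for t, c in self.converged_by_form.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# orchestration per method
# ---------------------------------------------------------------------------

def _ordered_anchor_lists(
    cal_ref: Mapping[str, float], cal_new: Mapping[str, float], ids: Iterable[str]
) -> tuple[list[str], list[float], list[float]]:
    ids = sorted(ids)  # anchor matching by global id, order-insensitive
    missing = [i for i in ids if i not in cal_ref or i not in cal_new]
    if missing:
        raise ConfigurationError(f"anchors missing from calibrations: {missing}")
    return ids, [cal_new[i] for i in ids], [cal_ref[i] for i in ids]


def run_separate_linking(
    method: str,
    calibrations: Sequence[CalibrationResult],
    anchor_sets: Mapping[int, frozenset[str]],
) -> LinkResult:
    """Chain mean/mean or weighted mean/mean links across free calibrations.

    ``calibrations[t-1]`` is the free fit of form t; ``anchor_sets[p]`` the
    common item ids of the pair linking forms (p, p+1).  Per-pair constants
    are computed on the free-calibration anchor estimates and accumulated to
    the t1 scale.
    """
    if method not in ("mean_mean", "weighted_mean_mean"):
        raise ConfigurationError(f"unknown separate linking method {method!r}")
    T = len(calibrations)
    constants = {}
    diagnostics = {}
    for p in range(1, T):
        ref, new = calibrations[p - 1], calibrations[p]
        ids, d_new, d_ref = _ordered_anchor_lists(
            ref.difficulties, new.difficulties, anchor_sets[p]
        )
        if method == "mean_mean":
            constants[p] = mean_mean_constant(d_new, d_ref)
        else:
            se_new = [new.se[i] for i in ids]
            se_ref = [ref.se[i] for i in ids]
            if any(s is None or not np.isfinite(s) for s in se_new + se_ref):
                raise ValueError("weighted mean/mean requires finite anchor SEs")
            constants[p] = weighted_mean_mean_constant(
                d_new, se_new, d_ref, se_ref, weighting="pooled_difference"
            )
        diagnostics[p] = {
            "anchor_mean_ref": float(np.mean(d_ref)),
            "anchor_mean_new": float(np.mean(d_new)),
        }
    V = chain_links([constants[p] for p in range(1, T)])
    linked_difficulties = {}
    for t in range(1, T + 1):
        linked = apply_link(calibrations[t - 1], V[t - 1])
        # later forms overwrite anchors they share with the previous form
        linked_difficulties.update(linked.difficulties)
    return LinkResult(
        method=method,
        timepoints=list(range(1, T + 1)),
        mu={t: (calibrations[t - 1].mu or 0.0) + V[t - 1] for t in range(1, T + 1)},
        sigma2={t: calibrations[t - 1].sigma2 for t in range(1, T + 1)},
        per_pair_constants=constants,
        cumulative_constants={t: V[t - 1] for t in range(1, T + 1)},
        anchor_ids=dict(anchor_sets),
        converged_by_form={t: calibrations[t - 1].converged for t in range(1, T + 1)},
        linked_difficulties=linked_difficulties,
        diagnostics=diagnostics,
    )


def run_fpc(
    responses_by_form: Sequence[ResponseMatrix],
    anchor_sets: Mapping[int, frozenset[str]],
    spec: CalibrationSpec | None = None,
    first_fit: CalibrationResult | None = None,
) -> LinkResult:
    """Sequential fixed parameter calibration across the form chain.

    Form t1 is calibrated freely (mean 0); each subsequent form is calibrated
    with its anchors fixed at the previous form's common-scale estimates while
    its latent mean and variance are estimated, so the chain is carried by the
    fixing itself.  ``first_fit`` may supply an existing free calibration of
    form t1 to avoid refitting.
    """
    base = spec or CalibrationSpec()
    T = len(responses_by_form)
    fits: list[CalibrationResult] = []
    for t in range(1, T + 1):
        if t == 1:
            fit = first_fit or fit_mml_em(
                responses_by_form[0],
                CalibrationSpec(
                    mode="free", quadrature=base.quadrature, n_nodes=base.n_nodes,
                    max_iter=base.max_iter, tol=base.tol, loglik_tol=base.loglik_tol,
                ),
            )
        else:
            prev = fits[-1]
            fixed = {
                i: prev.difficulties[i]
                for i in anchor_sets[t - 1]
                if i in prev.difficulties
            }
            if not fixed:
                raise ConfigurationError(f"no anchors available to fix for form t{t}")
            fit = fit_mml_em(
                responses_by_form[t - 1],
                CalibrationSpec(
                    mode="fixed_anchor", fixed_items=fixed,
                    quadrature=base.quadrature, n_nodes=base.n_nodes,
                    max_iter=base.max_iter, tol=base.tol, loglik_tol=base.loglik_tol,
                ),
            )
        fits.append(fit)
    linked_difficulties = {}
    for fit in fits:
        linked_difficulties.update(fit.difficulties)
    return LinkResult(
        method="fpc",
        timepoints=list(range(1, T + 1)),
        mu={t: fits[t - 1].mu for t in range(1, T + 1)},
        sigma2={t: fits[t - 1].sigma2 for t in range(1, T + 1)},
        cumulative_constants={t: fits[t - 1].mu for t in range(1, T + 1)},
        anchor_ids=dict(anchor_sets),
        converged_by_form={t: fits[t - 1].converged for t in range(1, T + 1)},
        linked_difficulties=linked_difficulties,
        diagnostics={"fits": [f.scalar_table() for f in fits]},
    )


def run_concurrent(
    responses_by_form: Sequence[ResponseMatrix],
    anchor_sets: Mapping[int, frozenset[str]] | None = None,
    spec: CalibrationSpec | None = None,
) -> LinkResult:
    """Concurrent calibration of all forms; moments read from the joint fit.

    Non-convergence is flagged on the result, never raised.
    """
    fit = fit_concurrent(list(responses_by_form), spec or CalibrationSpec(mode="concurrent"))
    timepoints = sorted(fit.mu_by_form)
    return LinkResult(
        method="concurrent",
        timepoints=timepoints,
        mu=dict(fit.mu_by_form),
        sigma2=dict(fit.sigma2_by_form),
        anchor_ids=dict(anchor_sets or {}),
        converged_by_form={t: fit.converged for t in timepoints},
        linked_difficulties=dict(fit.difficulties),
        diagnostics={"n_iter": fit.n_iter, "loglik": fit.loglik},
    )
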