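"""Malthusian fitness estimation from marked-competitor assays.

A focal (non-fluorescent) strain is mixed with a YFP-marked common
competitor and propagated through daily 1:101 transfers. If m is the
Malthusian parameter of the focal strain minus the competitor's (per
generation), the non-fluorescent fraction follows

    NonFluor(T) = p0 * e^{mT} / (p0 * e^{mT} + 1 - p0),

equivalently logit(NonFluor) = logit(p0) + m*T, where T is elapsed
generations (day * log2(dilution)). The fit minimises squared error on
the fraction scale by Gauss-Newton with an analytic Jacobian, matching a
nonlinear least-squares fit of the model as written; the exact logit
linearity is used for initialisation (and as an independent oracle in
tests).
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import CompetitionAssay, ConvergenceError, FitResult, SaturatedAssayError

__all__ = [
    "predicted_fraction",
    "generations_from_day",
    "fit_competition",
    "fitness_table",
]


def predicted_fraction(p0: float, m: float, T) -> float:
    """Model non-fluorescent fraction after T generations.

    Strictly increasing in T iff m > 0; returns p0 exactly at T = 0.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    T = np.asarray(T, dtype=float)
    # compute on the logit scale for numerical range safety
    z = math.log(p0 / (1.0 - p0)) + m * T
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


def generations_from_day(day: float, dilution: float = 101.0) -> float:
    """Elapsed generations after ``day`` daily 1:D transfers: day * log2(D)."""
    if dilution <= 1:
        raise ValueError("dilution must be > 1")
    if day < 0:
        raise ValueError("day must be >= 0")
    return day * math.log2(dilution)


def _model_and_jacobian(p0: float, m: float, T: np.ndarray):
    f = predicted_fraction(p0, m, np.asarray(T))
    f = np.atleast_1d(f)
    fq = f * (1.0 - f)
    J = np.column_stack([fq / (p0 * (1.0 - p0)), fq * T])
    return f, J


def fit_competition(assay: CompetitionAssay, max_iter: int = 200) -> FitResult:
    """Least-squares estimate of (p0, m) from one competition trajectory.

    Initialisation: p0 from the earliest observation, m from an ordinary
    least-squares fit of logit(fraction) on T (fractions clipped to
    [1/(n+1), n/(n+1)] per observation). Gauss-Newton with step halving
    refines on the fraction scale; convergence when the parameter step
    falls below 1e-10.

    Raises
    ------
    SaturatedAssayError
        If every observed fraction is 0 or every fraction is 1.
    ConvergenceError
        After ``max_iter`` iterations without convergence (diagnostics
        attached).
    """
    T = assay.T
    y = assay.fractions
    ntot = (assay.n_nonfluor + assay.n_fluor).astype(float)
    if np.all(y == 0.0) or np.all(y == 1.0):
        raise SaturatedAssayError("saturated assay: fractions are all 0 or all 1")

    yc = np.clip(y, 1.0 / (ntot + 1.0), ntot / (ntot + 1.0))
    logit = np.log(yc / (1.0 - yc))
    p0 = float(np.clip(yc[int(np.argmin(T))], 1e-6, 1.0 - 1e-6))
    m = float(np.polyfit(T, logit, 1)[0])

    params = np.array([p0, m])
    f, _ = _model_and_jacobian(*params, T)
    rss = float(np.sum((y - f) ** 2))
    for _ in range(max_iter):
        f, J = _model_and_jacobian(*params, T)
        resid = y - f
        delta, *_ = np.linalg.lstsq(J, resid, rcond=None)
        step = 1.0
        accepted = False
        for _ in range(40):
            cand = params + step * delta
            cand[0] = float(np.clip(cand[0], 1e-9, 1.0 - 1e-9))
            fc = np.atleast_1d(predicted_fraction(cand[0], cand[1], T))
            rss_c = float(np.sum((y - fc) ** 2))
            if rss_c <= rss + 1e-18:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # no descent direction left: treat as converged at a minimum
            break
        moved = float(np.linalg.norm(cand - params))
        params, rss = cand, rss_c
        if moved < 1e-10:
            break
    else:
        raise ConvergenceError(
            "competition fit did not converge",
            diagnostics={"params": params.tolist(), "rss": rss, "n_obs": int(T.size)},
        )
    return FitResult(
        p0_hat=float(params[0]), m_hat=float(params[1]), rss=rss, n_obs=int(T.size)
    )


def fitness_table(
    assays: Sequence[CompetitionAssay],
    metadata: Optional[Mapping[str, Mapping]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every replicate and summarise Malthusian differences per colony.

    ``metadata`` maps ``replicate_id`` to a dict with at least
    ``colony_id`` (optionally ``ploidy`` and ``generation``). Replicates
    whose fit fails are kept as flagged rows with NaN estimates rather
    than dropped.

    Returns ``(replicates, colonies)``: per-replicate fits and per-colony
    mean +/- SE of m over replicates.
    """
    if not assays:
        raise ValueError("need at least one assay")
    metadata = metadata or {}
    rows = []
    for assay in assays:
        info = dict(metadata.get(assay.replicate_id, {}))
        row = {
            "replicate_id": assay.replicate_id,
            "colony_id": info.get("colony_id", assay.replicate_id),
            "ploidy": info.get("ploidy", np.nan),
            "generation": info.get("generation", np.nan),
            "flag": "",
        }
        try:
            fit = fit_competition(assay)
            row.update(
                p0_hat=fit.p0_hat, m_hat=fit.m_hat, rss=fit.rss, n_obs=fit.n_obs
            )
        except (SaturatedAssayError, ConvergenceError) as exc:
            row.update(p0_hat=np.nan, m_hat=np.nan, rss=np.nan, n_obs=assay.T.size)
            row["flag"] = type(exc).__name__
        rows.append(row)
    reps = pd.DataFrame(rows).sort_values("replicate_id").reset_index(drop=True)

    ok = reps[reps["flag"] == ""]
    colonies = (
        ok.groupby(["colony_id", "ploidy"], dropna=False)["m_hat"]
        .agg(
            n_replicates="count",
            m_mean="mean",
            m_se=lambda v: float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
        )
        .reset_index()
        .sort_values("colony_id")
        .reset_index(drop=True)
    )
    return reps, colonies
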