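"""Step 1 of the pipeline: the integrated step-selection function (ISSF).

GPS fixes are regularized onto their nominal schedule, converted into
realized steps, and each realized step is contrasted with matched random
steps (a *stratum*). Random steps draw turning angles from U(-pi, pi) and
step lengths from a gamma distribution fitted to the realized steps. The
selection score of a step is

    w(x) = exp(beta_1 x_1 + ... + beta_p x_p)

and the probability that step i is the realized one in its stratum is
w(x_i) / sum_j w(x_j); maximizing the product of these per-stratum
probabilities is fixed-effects conditional logistic regression, implemented
here with an analytic gradient and observed-information covariance.

Tables of steps are pandas DataFrames with one row per step; strata carry
``stratum`` and ``case`` columns (exactly one ``case == 1`` row per stratum).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import OutOfBoundsError, SeparationWarning, SimulationError
from .landscape import CovariateStack, extract_along_segments

logger = logging.getLogger(__name__)

FOUR_HOURS = pd.Timedelta(hours=4)
FIFTEEN_MIN = pd.Timedelta(minutes=15)

#: Movement covariates computed for every step.
MOVEMENT_COVARIATES = ("sl", "log_sl", "cos_ta")

#: Local clock window of low activity (hot midday hours), [start, end).
LOW_ACTIVITY_WINDOW = (9.0, 17.0)


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class GammaStepLength:
    """Gamma step-length distribution (shape ``k``, scale ``theta`` in m)."""

    k: float
    theta: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.theta <= 0:
            raise ValueError("gamma shape and scale must be > 0")

    @property
    def mean(self) -> float:
        return self.k * self.theta

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.gamma(self.k, self.theta, size=n)

    def cdf(self, x) -> np.ndarray:
        return stats.gamma.cdf(x, a=self.k, scale=self.theta)


@dataclass
class MovementModel:
    """Fitted ISSF: terms, coefficients, and everything needed to simulate.

    ``standardization`` maps covariate names to the ``(mean, sd)`` used to
    scale them during fitting; the simulator applies the same table so that
    simulated candidate steps live on the fitted scale. ``gamma`` is the
    step-length proposal distribution.
    """

    terms: list[str]
    beta: np.ndarray
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    gamma: GammaStepLength | None = None
    n_random: int = 24
    loglik: float | None = None
    vcov: pd.DataFrame | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.terms) != self.beta.size:
            raise ValueError("terms and beta must have equal length")
        for name, (_, sd) in self.standardization.items():
            if sd <= 0:
                raise ValueError(f"standardization sd for {name!r} must be > 0")

    def se(self) -> pd.Series:
        if self.vcov is None:
            raise ValueError("model has no covariance table")
        return pd.Series(np.sqrt(np.diag(self.vcov.values)), index=self.terms, name="se")

    def summary(self) -> pd.DataFrame:
        se = self.se()
        z = self.beta / se.values
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": se.values,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=self.terms,
        )

    def linear_predictor(self, frame) -> np.ndarray:
        return design_matrix(frame, self.terms) @ self.beta

    def beta_raw(self) -> pd.Series:
        """Main-effect coefficients on the raw covariate scale.

        A coefficient fitted on ``(x - m) / s`` equals ``s`` times the raw-
        scale coefficient; interactions of standardized columns have no
        single raw-scale equivalent and are reported as NaN.
        """
        out = {}
        for term, b in zip(self.terms, self.beta):
            if ":" in term:
                out[term] = np.nan
            elif term in self.standardization:
                out[term] = b / self.standardization[term][1]
            else:
                out[term] = b
        return pd.Series(out, name="beta_raw")

    def updated_gamma(self) -> GammaStepLength:
        """Step-length distribution corrected by the fitted sl/log_sl terms.

        With a gamma(k, theta) proposal, raw-scale coefficients b_sl and
        b_log_sl tilt the kernel to gamma(k + b_log_sl, 1/(1/theta - b_sl)).
        """
        if self.gamma is None:
            raise ValueError("model has no gamma proposal")
        raw = self.beta_raw()
        b_sl = raw.get("sl", 0.0)
        b_lsl = raw.get("log_sl", 0.0)
        b_sl = 0.0 if pd.isna(b_sl) else b_sl
        b_lsl = 0.0 if pd.isna(b_lsl) else b_lsl
        return GammaStepLength(
            k=self.gamma.k + b_lsl, theta=1.0 / (1.0 / self.gamma.theta - b_sl)
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "terms": list(self.terms),
            "beta": self.beta.tolist(),
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "gamma": None if self.gamma is None else {"k": self.gamma.k, "theta": self.gamma.theta},
            "n_random": self.n_random,
            "loglik": self.loglik,
            "vcov": None if self.vcov is None else self.vcov.values.tolist(),
            "converged": self.converged,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MovementModel":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            doc = json.loads(Path(source).read_text())
        else:
            doc = json.loads(source)
        vcov = doc.get("vcov")
        terms = doc["terms"]
        return cls(
            terms=terms,
            beta=np.asarray(doc["beta"], dtype=float),
            standardization={k: tuple(v) for k, v in doc["standardization"].items()},
            gamma=None if doc.get("gamma") is None else GammaStepLength(**doc["gamma"]),
            n_random=doc.get("n_random", 24),
            loglik=doc.get("loglik"),
            vcov=None if vcov is None else pd.DataFrame(vcov, index=terms, columns=terms),
            converged=doc.get("converged", True),
        )


@dataclass
class CVResult:
    """k-fold case-control cross-validation summary.

    ``rs_realized`` / ``rs_random`` hold (mean, lo, hi) of the Spearman
    correlation between rank and rank frequency across the k*reps folds;
    rank 1 is the highest selection score, so a predictive model yields a
    strongly *negative* correlation.
    """

    rank_freq: pd.Series
    rs_realized: tuple[float, float, float]
    rs_random: tuple[float, float, float]
    rs_realized_values: np.ndarray
    rs_random_values: np.ndarray


# ---------------------------------------------------------------------------
# GPS preprocessing


def _require_columns(frame: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def regularize_fixes(
    fixes: pd.DataFrame,
    interval: pd.Timedelta = FOUR_HOURS,
    tol: pd.Timedelta = FIFTEEN_MIN,
) -> pd.DataFrame:
    """Keep fixes that sit on the nominal fix schedule.

    The first fix of each individual is kept; a later fix is kept when its
    lag from the previous *kept* fix is within ``tol`` of a positive multiple
    of ``interval`` (a missed fix does not disqualify the rest of the
    schedule). Dropped fixes are counted in the log.
    """
    _require_columns(fixes, ("individual", "t", "x", "y"), "fixes")
    if len(fixes) == 0:
        return fixes.copy()
    keep_parts = []
    n_dropped = 0
    for ind, grp in fixes.groupby("individual", sort=False):
        t = pd.to_datetime(grp["t"]).reset_index(drop=True)
        if not t.is_monotonic_increasing:
            raise ValueError(f"timestamps of individual {ind!r} are not increasing")
        keep = np.zeros(len(grp), dtype=bool)
        keep[0] = True
        t_prev = t.iloc[0]
        for pos in range(1, len(grp)):
            dt = t.iloc[pos] - t_prev
            k = max(1, round(dt / interval))
            if abs(dt - k * interval) <= tol:
                keep[pos] = True
                t_prev = t.iloc[pos]
        n_dropped += int((~keep).sum())
        keep_parts.append(grp.iloc[keep])
    if n_dropped:
        logger.info("regularize_fixes dropped %d off-schedule fixes", n_dropped)
    return pd.concat(keep_parts, ignore_index=True)


def fixes_to_steps(
    fixes: pd.DataFrame,
    interval: pd.Timedelta = FOUR_HOURS,
    tol: pd.Timedelta = FIFTEEN_MIN,
) -> pd.DataFrame:
    """Convert regularized fixes into realized steps of equal duration.

    Each consecutive fix pair whose duration is within ``interval +/- tol``
    becomes one step; turning angles are computed against the previous
    retained step of the same individual, and a gap leaves ``cos_ta`` (and
    ``prev_heading``) undefined (NaN). Zero-length steps are dropped because
    ``log(sl)`` is undefined.
    """
    _require_columns(fixes, ("individual", "t", "x", "y"), "fixes")
    rows = []
    n_zero = 0
    for ind, grp in fixes.groupby("individual", sort=False):
        grp = grp.reset_index(drop=True)
        t = pd.to_datetime(grp["t"])
        prev_heading = np.nan
        prev_end_time = None
        for a in range(len(grp) - 1):
            dt = t.iloc[a + 1] - t.iloc[a]
            if abs(dt - interval) > tol:
                continue
            x0, y0 = float(grp["x"].iloc[a]), float(grp["y"].iloc[a])
            x1, y1 = float(grp["x"].iloc[a + 1]), float(grp["y"].iloc[a + 1])
            sl = float(np.hypot(x1 - x0, y1 - y0))
            if sl == 0.0:
                n_zero += 1
                prev_end_time = None  # breaks the heading chain
                continue
            heading = float(np.arctan2(y1 - y0, x1 - x0))
            contiguous = prev_end_time is not None and t.iloc[a] == prev_end_time
            ph = prev_heading if contiguous else np.nan
            rows.append(
                {
                    "individual": ind,
                    "t_start": t.iloc[a],
                    "x_start": x0,
                    "y_start": y0,
                    "x_end": x1,
                    "y_end": y1,
                    "sl": sl,
                    "log_sl": float(np.log(sl)),
                    "heading": heading,
                    "prev_heading": ph,
                    "cos_ta": float(np.cos(heading - ph)) if np.isfinite(ph) else np.nan,
                }
            )
            prev_heading = heading
            prev_end_time = t.iloc[a + 1]
    if n_zero:
        logger.warning("fixes_to_steps dropped %d zero-length (stationary) steps", n_zero)
    return pd.DataFrame(rows)


def fit_gamma(step_lengths) -> GammaStepLength:
    """Maximum-likelihood gamma fit (location fixed at 0) to step lengths."""
    x = np.asarray(step_lengths, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 step lengths")
    if np.any(x <= 0):
        raise ValueError("step lengths must be > 0")
    if np.ptp(x) == 0:
        raise ValueError("step lengths are constant; gamma fit is degenerate")
    k, _, theta = stats.gamma.fit(x, floc=0)
    return GammaStepLength(k=float(k), theta=float(theta))


def is_low_activity(t) -> int:
    """1 when the local clock time falls in the low-activity window."""
    ts = pd.Timestamp(t)
    h = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    lo, hi = LOW_ACTIVITY_WINDOW
    return int(lo <= h < hi)


# ---------------------------------------------------------------------------
# Random steps and strata


def sample_random_steps(
    start,
    prev_heading: float,
    n: int,
    gamma: GammaStepLength,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw ``n`` random steps from ``start`` given the previous heading.

    Turning angles are uniform on (-pi, pi) relative to ``prev_heading`` and
    lengths follow the gamma proposal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ta = rng.uniform(-np.pi, np.pi, size=n)
    sl = np.maximum(gamma.rvs(n, rng), 1e-9)
    heading = prev_heading + ta
    x0, y0 = float(start[0]), float(start[1])
    return pd.DataFrame(
        {
            "x_start": x0,
            "y_start": y0,
            "x_end": x0 + sl * np.cos(heading),
            "y_end": y0 + sl * np.sin(heading),
            "sl": sl,
            "log_sl": np.log(sl),
            "heading": heading,
            "cos_ta": np.cos(ta),
        }
    )


def build_strata(
    realized: pd.DataFrame,
    stack: CovariateStack,
    n_random: int,
    gamma: GammaStepLength,
    rng: np.random.Generator,
    resample_cap: int = 10_000,
    spacing: float | None = None,
) -> pd.DataFrame:
    """Pair each realized step with ``n_random`` random steps.

    Realized steps without a defined previous heading (post-gap) are skipped.
    Random steps whose segment leaves the grid are redrawn individually, as
    during simulation; habitat covariates are extracted along every step and
    ``low_activity`` is set from the stratum's start time.
    """
    _require_columns(
        realized,
        ("x_start", "y_start", "x_end", "y_end", "sl", "log_sl", "prev_heading", "t_start"),
        "realized steps",
    )
    grid = stack.grid
    usable = realized[np.isfinite(realized["prev_heading"].to_numpy(dtype=float))]
    usable = usable[
        grid.contains(usable["x_start"].to_numpy(), usable["y_start"].to_numpy())
        & grid.contains(usable["x_end"].to_numpy(), usable["y_end"].to_numpy())
    ].reset_index(drop=True)
    if len(usable) == 0:
        raise ValueError("no realized steps with a defined previous heading inside the grid")
    frames = []
    for s, row in usable.iterrows():
        start = (row["x_start"], row["y_start"])
        rand = sample_random_steps(start, row["prev_heading"], n_random, gamma, rng)
        inside = grid.contains(rand["x_end"].to_numpy(), rand["y_end"].to_numpy())
        attempts = 0
        while not inside.all():
            bad = np.flatnonzero(~inside)
            attempts += bad.size
            if attempts > resample_cap:
                raise SimulationError(
                    f"exceeded {resample_cap} redraws for random steps at {start}"
                )
            redraw = sample_random_steps(start, row["prev_heading"], bad.size, gamma, rng)
            rand.iloc[bad] = redraw.to_numpy()
            inside = grid.contains(rand["x_end"].to_numpy(), rand["y_end"].to_numpy())
        case = pd.DataFrame(
            {
                "x_start": [row["x_start"]],
                "y_start": [row["y_start"]],
                "x_end": [row["x_end"]],
                "y_end": [row["y_end"]],
                "sl": [row["sl"]],
                "log_sl": [row["log_sl"]],
                "heading": [row["heading"]],
                "cos_ta": [np.cos(row["heading"] - row["prev_heading"])],
            }
        )
        part = pd.concat([case, rand], ignore_index=True)
        part.insert(0, "case", [1] + [0] * n_random)
        part.insert(0, "stratum", s)
        part["t_start"] = row["t_start"]
        part["low_activity"] = is_low_activity(row["t_start"])
        if "individual" in usable.columns:
            part["individual"] = row["individual"]
        frames.append(part)
    strata = pd.concat(frames, ignore_index=True)
    habitat = extract_along_segments(
        stack,
        strata["x_start"].to_numpy(),
        strata["y_start"].to_numpy(),
        strata["x_end"].to_numpy(),
        strata["y_end"].to_numpy(),
        spacing=spacing,
    )
    for name, values in habitat.items():
        strata[name] = values
    return strata


# ---------------------------------------------------------------------------
# Standardization and design matrices


def standardize(
    strata: pd.DataFrame, covariates: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Scale covariates to zero mean, unit sd over all (realized + random) steps."""
    out = strata.copy()
    table: dict[str, tuple[float, float]] = {}
    for name in covariates:
        if name not in out.columns:
            raise ValueError(f"covariate {name!r} not present")
        x = out[name].to_numpy(dtype=float)
        m = float(np.nanmean(x))
        s = float(np.nanstd(x, ddof=0))
        if s == 0.0:
            raise ValueError(f"covariate {name!r} has zero standard deviation")
        out[name] = (x - m) / s
        table[name] = (m, s)
    return out, table


def apply_standardization(frame, table: Mapping[str, tuple[float, float]]):
    """Apply a stored (mean, sd) table; works on DataFrames or dicts of arrays."""
    if isinstance(frame, pd.DataFrame):
        out = frame.copy()
    else:
        out = dict(frame)
    for name, (m, s) in table.items():
        if (name in out.columns) if isinstance(out, pd.DataFrame) else (name in out):
            out[name] = (np.asarray(out[name], dtype=float) - m) / s
    return out


def invert_standardization(frame, table: Mapping[str, tuple[float, float]]):
    if isinstance(frame, pd.DataFrame):
        out = frame.copy()
    else:
        out = dict(frame)
    for name, (m, s) in table.items():
        if (name in out.columns) if isinstance(out, pd.DataFrame) else (name in out):
            out[name] = np.asarray(out[name], dtype=float) * s + m
    return out


def design_matrix(frame, terms: Sequence[str]) -> np.ndarray:
    """Build the (n_steps, n_terms) design; ``a:b`` terms are products."""

    def col(name: str) -> np.ndarray:
        if isinstance(frame, pd.DataFrame):
            if name not in frame.columns:
                raise KeyError(f"term component {name!r} not in frame")
            return frame[name].to_numpy(dtype=float)
        if name not in frame:
            raise KeyError(f"term component {name!r} not in frame")
        return np.asarray(frame[name], dtype=float)

    cols = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            cols.append(col(a) * col(b))
        else:
            cols.append(col(term))
    return np.column_stack(cols) if cols else np.empty((len(frame), 0))


def default_candidate_terms(habitat: Sequence[str]) -> list[str]:
    """Movement-by-habitat interaction candidates for forward selection."""
    partners = list(habitat) + ["low_activity"]
    out = [f"{m}:{h}" for m in MOVEMENT_COVARIATES for h in partners]
    out += ["cos_ta:sl", "cos_ta:log_sl"]
    return out


# ---------------------------------------------------------------------------
# Conditional logistic likelihood


def selection_score(beta, x) -> float:
    """Selection score w(x) = exp(beta . x)."""
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    if beta.shape != x.shape:
        raise ValueError(f"beta has shape {beta.shape}, x has shape {x.shape}")
    return float(np.exp(beta @ x))


def stratum_probabilities(beta, X) -> np.ndarray:
    """Within-stratum realization probabilities (softmax of linear predictors)."""
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    if eta.size == 0:
        raise ValueError("stratum is empty")
    eta = eta - eta.max()
    w = np.exp(eta)
    return w / w.sum()


class _ClogitData:
    """Sorted design with per-stratum boundaries for fast likelihood sums."""

    def __init__(self, strata: pd.DataFrame, terms: Sequence[str]):
        _require_columns(strata, ("stratum", "case"), "strata")
        frame = strata.sort_values("stratum", kind="stable").reset_index(drop=True)
        self.terms = list(terms)
        self.X = design_matrix(frame, self.terms)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix contains non-finite values")
        codes, _ = pd.factorize(frame["stratum"], sort=False)
        self.seg = codes
        self.starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        self.n_strata = self.starts.size
        case = frame["case"].to_numpy(dtype=int)
        per = np.add.reduceat(case, self.starts)
        if not np.all(per == 1):
            raise ValueError("every stratum must contain exactly one realized step")
        self.case_idx = np.flatnonzero(case == 1)

    def check_within_stratum_variation(self) -> None:
        for t, x in zip(self.terms, self.X.T):
            mean = np.add.reduceat(x, self.starts) / np.add.reduceat(
                np.ones_like(x), self.starts
            )
            if np.allclose(x, mean[self.seg], atol=1e-12):
                raise ValueError(
                    f"term {t!r} has no within-stratum variation; it cancels out of "
                    "the conditional likelihood (use it inside an interaction)"
                )

    def nll_grad(self, beta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = self.X @ beta
        gmax = np.maximum.reduceat(eta, self.starts)
        ez = np.exp(eta - gmax[self.seg])
        Z = np.add.reduceat(ez, self.starts)
        nll = -(eta[self.case_idx].sum() - (np.log(Z) + gmax).sum())
        p = ez / Z[self.seg]
        grad = (p[:, None] * self.X).sum(axis=0) - self.X[self.case_idx].sum(axis=0)
        return float(nll), grad

    def hessian(self, beta: np.ndarray) -> np.ndarray:
        eta = self.X @ beta
        gmax = np.maximum.reduceat(eta, self.starts)
        ez = np.exp(eta - gmax[self.seg])
        Z = np.add.reduceat(ez, self.starts)
        p = ez / Z[self.seg]
        pX = p[:, None] * self.X
        H = self.X.T @ pX
        m = np.add.reduceat(pX, self.starts, axis=0)
        H -= m.T @ m
        return H


def clogit_negloglik(beta, strata: pd.DataFrame, terms: Sequence[str]):
    """Negative conditional log-likelihood and its analytic gradient."""
    data = _ClogitData(strata, terms)
    return data.nll_grad(np.asarray(beta, dtype=float))


def fit_clogit(
    strata: pd.DataFrame,
    terms: Sequence[str],
    gamma: GammaStepLength | None = None,
    standardization: Mapping[str, tuple[float, float]] | None = None,
    n_random: int | None = None,
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> MovementModel:
    """Maximize the conditional likelihood by quasi-Newton from beta = 0."""
    data = _ClogitData(strata, terms)
    data.check_within_stratum_variation()
    res = optimize.minimize(
        data.nll_grad,
        x0=np.zeros(len(data.terms)),
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    # Polish with analytic-Hessian Newton steps; BFGS line searches often
    # stall just above a tight gradient tolerance.
    beta = res.x
    nll, grad = data.nll_grad(beta)
    converged = bool(np.max(np.abs(grad)) < gtol)
    for _ in range(50):
        if converged:
            break
        try:
            step = np.linalg.solve(data.hessian(beta), grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            nll_new, grad_new = data.nll_grad(cand)
            if nll_new <= nll:
                beta, nll, grad = cand, nll_new, grad_new
                break
            scale /= 2
        else:
            break
        converged = bool(np.max(np.abs(grad)) < gtol)
    if not converged or np.any(np.abs(beta) > 30):
        warnings.warn(
            "conditional logistic fit did not converge cleanly; estimates may be "
            "unbounded (separation)",
            SeparationWarning,
        )
    H = data.hessian(beta)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular observed information; model not identifiable") from exc
    if n_random is None:
        sizes = np.diff(np.r_[data.starts, len(data.seg)])
        n_random = int(sizes[0]) - 1
    return MovementModel(
        terms=list(terms),
        beta=beta,
        standardization=dict(standardization or {}),
        gamma=gamma,
        n_random=n_random,
        loglik=-float(nll),
        vcov=pd.DataFrame(vcov, index=list(terms), columns=list(terms)),
        converged=converged,
    )


def model_aic(model: MovementModel) -> float:
    return 2 * len(model.terms) - 2 * model.loglik


def forward_select(
    strata: pd.DataFrame,
    base_terms: Sequence[str],
    candidate_terms: Sequence[str],
    **fit_kwargs,
) -> tuple[MovementModel, pd.DataFrame]:
    """Greedy forward AIC search starting from the base model.

    At each round, every remaining candidate is added in turn; the candidate
    with the lowest AIC is accepted when it improves on the current AIC.
    The trace records the AIC, its improvement, and the Akaike weight of the
    accepted candidate within its round.
    """
    overlap = set(base_terms) & set(candidate_terms)
    if overlap:
        raise ValueError(f"candidates overlap base terms: {sorted(overlap)}")
    current = fit_clogit(strata, list(base_terms), **fit_kwargs)
    current_aic = model_aic(current)
    remaining = list(candidate_terms)
    trace = [
        {"term": "<base>", "aic": current_aic, "delta_aic": 0.0, "aic_weight": np.nan}
    ]
    while remaining:
        fits = {}
        for cand in remaining:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", SeparationWarning)
                    fits[cand] = fit_clogit(strata, list(current.terms) + [cand], **fit_kwargs)
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"candidate {cand!r} skipped: {exc}")
        if not fits:
            break
        aics = {c: model_aic(m) for c, m in fits.items()}
        best = min(aics, key=aics.get)
        if aics[best] >= current_aic:
            break
        rel = np.exp(-0.5 * (np.array(list(aics.values())) - aics[best]))
        weight = float(np.exp(0.0) / rel.sum())
        trace.append(
            {
                "term": best,
                "aic": aics[best],
                "delta_aic": aics[best] - current_aic,
                "aic_weight": weight,
            }
        )
        current = fits[best]
        current_aic = aics[best]
        remaining.remove(best)
    return current, pd.DataFrame(trace)


# ---------------------------------------------------------------------------
# Cross-validation


def kfold_cv(
    strata: pd.DataFrame,
    terms: Sequence[str],
    k: int = 5,
    reps: int = 100,
    rng: np.random.Generator | None = None,
    **fit_kwargs,
) -> CVResult:
    """k-fold case-control cross-validation (rank of the realized step).

    Per repetition, strata are randomly split into ``k`` folds; each fold is
    scored by a model fitted to the others and the realized step's rank among
    its stratum (1 = highest score, ties broken at random) is tabulated. The
    Spearman correlation between rank and rank frequency is computed per
    fold, and summarized by its mean and 95% percentile interval; a matching
    null draws ranks uniformly.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(rng)
    ids = strata["stratum"].unique()
    if len(ids) < k:
        raise ValueError("fewer strata than folds")
    max_size = int(strata.groupby("stratum").size().max())
    ranks_all = np.arange(1, max_size + 1)
    counts_total = np.zeros(max_size, dtype=np.int64)
    rs_real, rs_rand = [], []
    for _ in range(reps):
        perm = rng.permutation(ids)
        for fold_ids in np.array_split(perm, k):
            if len(fold_ids) == 0:
                raise ValueError("fold with no strata")
            test_mask = strata["stratum"].isin(fold_ids)
            train = strata[~test_mask]
            test = strata[test_mask]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SeparationWarning)
                model = fit_clogit(train, list(terms), **fit_kwargs)
            eta = model.linear_predictor(test)
            counts = np.zeros(max_size, dtype=np.int64)
            counts_null = np.zeros(max_size, dtype=np.int64)
            for _, idx in test.groupby("stratum").indices.items():
                e = eta[idx]
                case_pos = int(np.flatnonzero(test["case"].to_numpy()[idx] == 1)[0])
                greater = int((e > e[case_pos]).sum())
                ties = int(np.isclose(e, e[case_pos]).sum()) - 1
                rank = 1 + greater + int(rng.integers(0, ties + 1))
                counts[rank - 1] += 1
                counts_null[int(rng.integers(0, len(idx)))] += 1
            counts_total += counts
            rs_real.append(stats.spearmanr(ranks_all, counts).statistic)
            rs_rand.append(stats.spearmanr(ranks_all, counts_null).statistic)

    def summarize(v):
        v = np.asarray(v, dtype=float)
        return (float(np.mean(v)), float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    return CVResult(
        rank_freq=pd.Series(counts_total, index=ranks_all, name="frequency"),
        rs_realized=summarize(rs_real),
        rs_random=summarize(rs_rand),
        rs_realized_values=np.asarray(rs_real),
        rs_random_values=np.asarray(rs_rand),
    )


# ---------------------------------------------------------------------------
# High-level pipeline


def fit_issf(
    fixes: pd.DataFrame,
    stack: CovariateStack,
    n_random: int = 24,
    seed=0,
    terms: Sequence[str] | None = None,
    candidate_terms: Sequence[str] | None = None,
    select: bool = False,
    interval: pd.Timedelta = FOUR_HOURS,
    tol: pd.Timedelta = FIFTEEN_MIN,
):
    """Full step-1 pipeline: fixes -> steps -> strata -> fitted model.

    Returns ``(model, strata)`` where the strata are standardized. The
    default term set is the movement kernel (sl, log_sl, cos_ta) plus one
    main effect per habitat layer; with ``select=True`` a forward AIC search
    over movement-by-habitat interactions follows.
    """
    rng = np.random.default_rng(seed)
    fixes = regularize_fixes(fixes, interval, tol)
    steps = fixes_to_steps(fixes, interval, tol)
    if len(steps) == 0:
        raise ValueError("no usable steps after regularization")
    gamma = fit_gamma(steps["sl"].to_numpy())
    strata = build_strata(steps, stack, n_random, gamma, rng)
    continuous = list(MOVEMENT_COVARIATES) + stack.names
    strata_std, table = standardize(strata, continuous)
    if terms is None:
        terms = list(MOVEMENT_COVARIATES) + stack.names
    if select:
        cands = candidate_terms or default_candidate_terms(stack.names)
        model, _ = forward_select(
            strata_std, terms, cands, gamma=gamma, standardization=table, n_random=n_random
        )
    else:
        model = fit_clogit(
            strata_std, terms, gamma=gamma, standardization=table, n_random=n_random
        )
    return model, strata_std
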