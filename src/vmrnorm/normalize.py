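"""Linear-model normalization of systematic effects in plate activity data.

Plate-based behavioural assays carry three systematic nuisance effects that
mask biological differences between groups of larvae:

* **light-intensity variation** — wells at the plate centre receive more
  stimulus light than wells at the edge, and activity responds to intensity;
* **batch effects** — independent biological replicates (different day,
  different plate) shift activity additively;
* **baseline variation** — groups differ in pre-stimulus activity, which
  confounds comparisons of the stimulus response.

Each effect is removed by fitting a per-group linear model and keeping the
residuals:

* light:    ``activity ~ beta0 + beta_light * intensity``  (OLS per group);
* batch:    ``activity ~ beta0 + beta_batch[k]`` with the sum-to-zero
  constraint ``sum_k beta_batch[k] = 0``, so ``beta0`` is the unweighted
  grand mean of batch means and the fitted value for an observation equals
  its batch mean;
* baseline: ``activity ~ factor`` where ``factor = (group baseline-window
  mean) - target`` shifts every group's pre-stimulus mean to a common
  target.

Because residuals can be negative while activity is a non-negative
quantity, a non-negative offset ``mu_offset`` (default 0.06) is added after
subtraction. The integrated pipeline chains light -> batch -> baseline,
each step fitting on the previous step's residuals, with the offset applied
once at the final step.

The estimators follow scikit-learn conventions (``fit`` learns per-group
coefficients and resolves the offset; ``transform`` subtracts fitted
nuisance quantities). Module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from .plate_data import (
    DEFAULT_BASELINE_WINDOW,
    DEFAULT_GROUPING,
    join_light,
    subset_window,
)

__all__ = [
    "GroupFit",
    "OffsetPolicy",
    "NormalizationReport",
    "NormalizationError",
    "DegeneratePredictorError",
    "LightIntensityNormalizer",
    "BatchEffectNormalizer",
    "BaselineNormalizer",
    "IntegratedNormalizer",
    "fit_light_model",
    "fit_batch_model",
    "compute_baseline_target",
    "fit_baseline_factors",
    "apply_normalization",
    "integrated_normalize",
    "fits_to_frame",
    "fits_from_frame",
]


class NormalizationError(ValueError):
    """Invalid input to a normalization model."""


class DegeneratePredictorError(NormalizationError):
    """A model predictor has zero variance within a group."""


@dataclass(frozen=True)
class GroupFit:
    """Fitted normalization model for one group.

    ``group`` holds the values of the grouping columns named in
    ``grouping`` (e.g. ``('TL', 6, 'LightOn')`` under the default
    strain x stage x stimulus scheme). ``kind`` is one of ``light``,
    ``batch`` or ``baseline``. Coefficients, standard errors and two-sided
    p-values (t reference distribution with residual degrees of freedom)
    share the same name set.
    """

    group: tuple
    grouping: tuple
    kind: str
    coefficients: dict
    standard_errors: dict
    p_values: dict
    n_obs: int

    def __post_init__(self):
        names = set(self.coefficients)
        if set(self.standard_errors) != names or set(self.p_values) != names:
            raise ValueError("coefficient/SE/p-value name sets differ")
        if self.kind == "batch":
            effects = [v for k, v in self.coefficients.items()
                       if k.startswith("beta_batch[")]
            if effects and abs(sum(effects)) > 1e-10:
                raise ValueError(
                    f"batch effects do not sum to zero: {sum(effects)!r}")

    @property
    def batch_effects(self) -> dict:
        """Batch label -> effect, for ``kind='batch'`` fits."""
        return {
            k[len("beta_batch["):-1]: v
            for k, v in self.coefficients.items()
            if k.startswith("beta_batch[")
        }


@dataclass(frozen=True)
class OffsetPolicy:
    """How to choose the non-negativity offset ``mu_offset``.

    ``fixed`` uses ``value`` as-is. ``auto`` resolves the smallest offset
    that keeps every normalized activity non-negative
    (``mu = |min pre-offset value|`` when that minimum is negative, else 0),
    rounded up to 4 decimal places for reporting stability.
    """

    mode: str = "fixed"
    value: float = 0.06

    def __post_init__(self):
        if self.mode not in ("fixed", "auto"):
            raise ValueError(f"offset mode must be fixed|auto, got {self.mode!r}")
        if self.mode == "fixed" and self.value < 0:
            raise ValueError("fixed offset must be non-negative")

    def resolve(self, pre_offset_min: float) -> float:
        if self.mode == "fixed":
            return float(self.value)
        if pre_offset_min >= 0:
            return 0.0
        return math.ceil(-pre_offset_min * 1e4) / 1e4

    @classmethod
    def coerce(cls, offset) -> "OffsetPolicy":
        if isinstance(offset, OffsetPolicy):
            return offset
        if offset == "auto":
            return cls(mode="auto", value=0.0)
        return cls(mode="fixed", value=float(offset))


@dataclass
class NormalizationReport:
    """Audit trail of a normalization run."""

    fits: list = field(default_factory=list)
    offset_used: float = 0.0
    steps: list = field(default_factory=list)
    residual_summary: pd.DataFrame | None = None
    skipped_groups: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-group fitting engines

def _clean_key(key) -> tuple:
    """Group key as a tuple of plain Python scalars."""
    if not isinstance(key, tuple):
        key = (key,)
    return tuple(v.item() if hasattr(v, "item") else v for v in key)



def _collapse_to_larva_means(df: pd.DataFrame, extra: Sequence[str]) -> pd.DataFrame:
    keys = ["larva_id", "trial"] + list(extra)
    return df.groupby(keys, as_index=False, sort=False)["activity"].mean()


def _fit_light_group(y: np.ndarray, x: np.ndarray) -> tuple[dict, dict, dict]:
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("zero intensity variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    names = ("beta0", "beta_light")
    return (
        dict(zip(names, map(float, res.params))),
        dict(zip(names, map(float, res.bse))),
        dict(zip(names, map(float, res.pvalues))),
    )


def _fit_batch_group(y: np.ndarray, batches: np.ndarray):
    """One-way layout under sum-to-zero (effects) coding.

    The saturated cell-means model fits each batch by its sample mean; the
    intercept is then the *unweighted* mean of batch means, and each effect
    is (batch mean) - (intercept). SEs and p-values come from the pooled
    residual variance with N - K degrees of freedom.
    """
    levels = sorted(pd.unique(batches).tolist())
    K = len(levels)
    coef: dict = {}
    se: dict = {}
    pval: dict = {}
    if K == 1:
        res = sm.OLS(y, np.ones_like(y)).fit()
        coef["beta0"] = float(res.params[0])
        se["beta0"] = float(res.bse[0])
        pval["beta0"] = float(res.pvalues[0])
        name = f"beta_batch[{levels[0]}]"
        coef[name], se[name], pval[name] = 0.0, float("nan"), float("nan")
        return coef, se, pval, levels
    counts = pd.Series(batches).value_counts()
    singletons = [lv for lv in levels if counts.get(lv, 0) < 2]
    if singletons:
        warnings.warn(
            f"batch(es) {singletons} have a single observation; "
            "standard errors are unreliable", UserWarning, stacklevel=3)
    # sum-coded design: columns for levels[0..K-2]; last level coded -1
    X = np.ones((len(y), K))
    for j, lv in enumerate(levels[:-1]):
        X[:, j + 1] = np.where(batches == lv, 1.0,
                               np.where(batches == levels[-1], -1.0, 0.0))
    res = sm.OLS(y, X).fit()
    coef["beta0"] = float(res.params[0])
    se["beta0"] = float(res.bse[0])
    pval["beta0"] = float(res.pvalues[0])
    for j, lv in enumerate(levels[:-1]):
        name = f"beta_batch[{lv}]"
        coef[name] = float(res.params[j + 1])
        se[name] = float(res.bse[j + 1])
        pval[name] = float(res.pvalues[j + 1])
    # last effect is minus the sum of the others; its SE via the contrast
    contrast = np.zeros(K)
    contrast[1:] = -1.0
    tt = res.t_test(contrast)
    name = f"beta_batch[{levels[-1]}]"
    coef[name] = float(np.squeeze(tt.effect))
    se[name] = float(np.squeeze(tt.sd))
    pval[name] = float(np.squeeze(tt.pvalue))
    # enforce the zero-sum identity exactly against float drift
    drift = sum(v for k, v in coef.items() if k.startswith("beta_batch["))
    coef[name] -= drift
    return coef, se, pval, levels


# ---------------------------------------------------------------------------
# estimators


class LightIntensityNormalizer(BaseEstimator, TransformerMixin):
    """Remove the per-well light-intensity effect from activity traces.

    Fits, per group, an ordinary least-squares regression of per-second
    activity on the intensity (W/m^2) each larva's well receives, then
    subtracts the fitted value and adds the offset.

    Parameters
    ----------
    light_map : Series
        Per-well intensity; joined to the table by well address.
    grouping : sequence of str
        Columns defining independent fitting groups.
    window : (int, int) or None
        Fitting window in seconds relative to the light change; None fits
        on all records.
    fit_on : {"second", "larva_mean"}
        Regression observation unit: every larva x second sample, or one
        per-larva mean activity.
    min_group_size : int
        Groups with fewer observations are skipped (recorded, not fitted).
    offset : float, "auto", or OffsetPolicy
        Non-negativity offset policy; "auto" resolves the smallest
        sufficient offset on the training table.
    degenerate : {"raise", "intercept"}
        What to do when a group's intensity has zero variance: refuse
        ("raise", the default — the slope is unidentifiable), or fall back
        to an intercept-only fit with slope 0 ("intercept", used inside the
        integrated chain where a constant light map makes the step vacuous).

    Attributes
    ----------
    fits_ : list of GroupFit
    offset_used_ : float
    report_ : NormalizationReport
    """

    _kind = "light"

    def __init__(self, light_map=None, grouping=tuple(DEFAULT_GROUPING),
                 window=None, fit_on="second", min_group_size=3,
                 offset="auto", degenerate="raise"):
        self.light_map = light_map
        self.grouping = grouping
        self.window = window
        self.fit_on = fit_on
        self.min_group_size = min_group_size
        self.offset = offset
        self.degenerate = degenerate

    def fit(self, X: pd.DataFrame, y=None):
        if self.light_map is None and "light_intensity" not in X.columns:
            raise NormalizationError(
                "light normalization needs a light_map or a pre-joined "
                "light_intensity column")
        if self.fit_on not in ("second", "larva_mean"):
            raise ValueError(f"fit_on must be second|larva_mean, got {self.fit_on!r}")
        grouping = list(self.grouping)
        data = X if self.light_map is None else join_light(X, self.light_map)
        if self.window is not None:
            data = subset_window(data, *self.window)
        if self.fit_on == "larva_mean":
            data = _collapse_to_larva_means(
                data, grouping + ["light_intensity"])
        fits, skipped = [], []
        for key, sub in data.groupby(grouping, sort=True):
            key = _clean_key(key)
            if len(sub) < max(self.min_group_size, 3):
                skipped.append(key)
                warnings.warn(f"group {key} below minimum size; skipped",
                              UserWarning, stacklevel=2)
                continue
            x = sub["light_intensity"].to_numpy(float)
            a = sub["activity"].to_numpy(float)
            if np.ptp(x) == 0:
                if self.degenerate != "intercept":
                    raise DegeneratePredictorError(
                        f"group {key}: light intensity constant across wells")
                nan = float("nan")
                coef = {"beta0": float(a.mean()), "beta_light": 0.0}
                se = {"beta0": float(a.std(ddof=1) / math.sqrt(len(a))),
                      "beta_light": nan}
                p = {"beta0": nan, "beta_light": nan}
            else:
                coef, se, p = _fit_light_group(a, x)
            fits.append(GroupFit(key, tuple(grouping), "light",
                                 coef, se, p, len(sub)))
        if not fits:
            raise NormalizationError("no group large enough to fit")
        self.fits_ = fits
        ref = X
        if skipped:
            fitted_keys = {f.group for f in fits}
            mask = [tuple(k) in fitted_keys
                    for k in X[grouping].itertuples(index=False)]
            ref = X[np.asarray(mask)]
        _, report = apply_normalization(
            ref, fits, OffsetPolicy.coerce(self.offset),
            light_map=self.light_map)
        report.skipped_groups = skipped
        self.offset_used_ = report.offset_used
        self.report_ = report
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, _ = apply_normalization(
            X, self.fits_, OffsetPolicy("fixed", self.offset_used_),
            light_map=self.light_map)
        return out


class BatchEffectNormalizer(BaseEstimator, TransformerMixin):
    """Remove additive biological-replicate (batch) shifts per group.

    One-way sum-to-zero model: the fitted value for an observation in batch
    k is that batch's mean; subtracting it centres every batch of a group on
    the group's unweighted grand mean of batch means.
    """

    _kind = "batch"

    def __init__(self, grouping=tuple(DEFAULT_GROUPING), window=None,
                 fit_on="second", offset="auto"):
        self.grouping = grouping
        self.window = window
        self.fit_on = fit_on
        self.offset = offset

    def fit(self, X: pd.DataFrame, y=None):
        grouping = list(self.grouping)
        data = X if self.window is None else subset_window(X, *self.window)
        if self.fit_on == "larva_mean":
            data = _collapse_to_larva_means(data, grouping + ["batch"])
        fits = []
        for key, sub in data.groupby(grouping, sort=True):
            key = _clean_key(key)
            counts = sub.groupby("batch")["activity"].size()
            if (counts < 2).all():
                raise NormalizationError(
                    f"group {key}: no batch with >= 2 observations")
            coef, se, p, _ = _fit_batch_group(
                sub["activity"].to_numpy(float),
                sub["batch"].to_numpy())
            fits.append(GroupFit(key, tuple(grouping), "batch",
                                 coef, se, p, len(sub)))
        self.fits_ = fits
        _, report = apply_normalization(
            X, fits, OffsetPolicy.coerce(self.offset))
        self.offset_used_ = report.offset_used
        self.report_ = report
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, _ = apply_normalization(
            X, self.fits_, OffsetPolicy("fixed", self.offset_used_))
        return out


class BaselineNormalizer(BaseEstimator, TransformerMixin):
    """Shift each group's pre-stimulus mean activity to a common target.

    The per-group factor is ``(baseline-window mean) - target``; it is an
    intercept-only regression on the baseline window, subtracted from the
    whole trace. When ``target`` is None the grand mean of all baseline
    records across groups is used. A pure shift: within-group variance is
    untouched.
    """

    _kind = "baseline"

    def __init__(self, target=None, baseline_window=DEFAULT_BASELINE_WINDOW,
                 grouping=tuple(DEFAULT_GROUPING), offset="auto"):
        self.target = target
        self.baseline_window = baseline_window
        self.grouping = grouping
        self.offset = offset

    def fit(self, X: pd.DataFrame, y=None):
        grouping = list(self.grouping)
        self.target_ = (
            compute_baseline_target(X, self.baseline_window)
            if self.target is None else float(self.target))
        base = subset_window(X, *self.baseline_window)
        if base.empty:
            raise NormalizationError(
                f"no records in baseline window {self.baseline_window}")
        fits = []
        present = set()
        for key, sub in base.groupby(grouping, sort=True):
            key = _clean_key(key)
            present.add(key)
            a = sub["activity"].to_numpy(float)
            factor = float(a.mean()) - self.target_
            n = len(a)
            sem = float(a.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            if n > 1 and sem > 0:
                from scipy import stats
                p = float(2 * stats.t.sf(abs(factor) / sem, df=n - 1))
            else:
                p = float("nan")
            fits.append(GroupFit(key, tuple(grouping), "baseline",
                                 {"baseline_factor": factor},
                                 {"baseline_factor": sem},
                                 {"baseline_factor": p}, n))
        all_keys = {
            tuple(k) for k in
            X[grouping].drop_duplicates().itertuples(index=False)}
        absent = sorted(all_keys - present)
        if absent:
            raise NormalizationError(
                f"group(s) absent from baseline window: {absent}")
        self.fits_ = fits
        _, report = apply_normalization(
            X, fits, OffsetPolicy.coerce(self.offset))
        self.offset_used_ = report.offset_used
        self.report_ = report
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, _ = apply_normalization(
            X, self.fits_, OffsetPolicy("fixed", self.offset_used_))
        return out


class IntegratedNormalizer(BaseEstimator, TransformerMixin):
    """Chained light -> batch -> baseline normalization.

    Each step is fitted on the previous step's residuals. The intermediate
    steps use a zero offset (negative residuals are permitted internally);
    a single offset — 0.06 by default — is applied at the baseline step, so
    every group's baseline-window mean ends at ``target + offset``.
    """

    def __init__(self, light_map=None, grouping=tuple(DEFAULT_GROUPING),
                 window=None, baseline_window=DEFAULT_BASELINE_WINDOW,
                 target=None, fit_on="second", min_group_size=3,
                 offset=0.06):
        self.light_map = light_map
        self.grouping = grouping
        self.window = window
        self.baseline_window = baseline_window
        self.target = target
        self.fit_on = fit_on
        self.min_group_size = min_group_size
        self.offset = offset

    def fit(self, X: pd.DataFrame, y=None):
        # baseline target defaults to the raw table's baseline-window grand
        # mean, so the final traces sit at the familiar raw activity level
        target = (compute_baseline_target(X, self.baseline_window)
                  if self.target is None else float(self.target))
        self.light_ = LightIntensityNormalizer(
            light_map=self.light_map, grouping=self.grouping,
            window=self.window, fit_on=self.fit_on,
            min_group_size=self.min_group_size, offset=0.0,
            degenerate="intercept").fit(X)
        r1 = self.light_.transform(X)
        self.batch_ = BatchEffectNormalizer(
            grouping=self.grouping, window=self.window,
            fit_on=self.fit_on, offset=0.0).fit(r1)
        r2 = self.batch_.transform(r1)
        self.baseline_ = BaselineNormalizer(
            target=target, baseline_window=self.baseline_window,
            grouping=self.grouping, offset=self.offset).fit(r2)
        self.target_ = self.baseline_.target_
        self.offset_used_ = self.baseline_.offset_used_
        steps = [self.light_, self.batch_, self.baseline_]
        self.report_ = NormalizationReport(
            fits=[f for s in steps for f in s.fits_],
            offset_used=self.offset_used_,
            steps=["light", "batch", "baseline"],
            residual_summary=self.baseline_.report_.residual_summary,
            skipped_groups=self.light_.report_.skipped_groups,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = self.light_.transform(X)
        out = self.batch_.transform(out)
        out = self.baseline_.transform(out)
        prov = [f"integrated_normalize(offset={self.offset_used_})"]
        out.attrs["provenance"] = (
            list(X.attrs.get("provenance", [])) + prov)
        out["step_provenance"] = "light+batch+baseline"
        return out


# ---------------------------------------------------------------------------
# applying fits


def _subtracted_quantity(df: pd.DataFrame, fits: Sequence[GroupFit],
                         light_map=None) -> np.ndarray:
    """Per-record quantity to subtract, constant along each larva's trace."""
    kinds = {f.kind for f in fits}
    if len(kinds) != 1:
        raise NormalizationError(f"mixed fit kinds: {sorted(kinds)}")
    kind = kinds.pop()
    grouping = list(fits[0].grouping)
    by_group = {f.group: f for f in fits}
    data = df
    if kind == "light":
        if light_map is not None:
            data = join_light(df, light_map)
        elif "light_intensity" not in df.columns:
            raise NormalizationError(
                "light fits need a light_map or light_intensity column")
    sub = np.empty(len(data), dtype=float)
    # positional per-group blocks keep large tables fast
    for key, loc in data.groupby(grouping, sort=False).indices.items():
        key = _clean_key(key)
        f = by_group.get(key)
        if f is None:
            raise NormalizationError(f"no {kind} fit for group {key}")
        if kind == "light":
            intens = data["light_intensity"].to_numpy(float)[loc]
            sub[loc] = (f.coefficients["beta0"]
                        + f.coefficients["beta_light"] * intens)
        elif kind == "batch":
            eff = f.batch_effects
            try:
                shifts = np.array(
                    [eff[b] if b in eff else eff[str(b)]
                     for b in data["batch"].to_numpy()[loc]], dtype=float)
            except KeyError as e:
                raise NormalizationError(
                    f"group {key}: unseen batch label {e}") from None
            sub[loc] = f.coefficients["beta0"] + shifts
        elif kind == "baseline":
            sub[loc] = f.coefficients["baseline_factor"]
        else:
            raise NormalizationError(f"unknown fit kind: {kind}")
    return sub


def apply_normalization(
    table: pd.DataFrame,
    fits: Sequence[GroupFit],
    offset="auto",
    light_map=None,
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Subtract fitted nuisance quantities and add the resolved offset.

    ``normalized = activity - fitted_quantity + mu_offset`` for every record
    (the subtracted quantity is constant along each larva's trace). In auto
    mode the offset is resolved on this table so the output is guaranteed
    non-negative.
    """
    fits = list(fits)
    if not fits:
        raise NormalizationError("no fits supplied")
    policy = OffsetPolicy.coerce(offset)
    pre = table["activity"].to_numpy(float) - _subtracted_quantity(
        table, fits, light_map=light_map)
    mu = policy.resolve(float(pre.min()))
    if pre.min() + mu < 0 and policy.mode == "auto":
        raise AssertionError("auto offset failed to reach non-negativity")
    out = table.copy()
    out["activity"] = pre + mu
    kind = fits[0].kind
    prov = list(table.attrs.get("provenance", []))
    prov.append(f"normalize[{kind}](offset={mu})")
    out.attrs["provenance"] = prov
    out["step_provenance"] = (
        out["step_provenance"] + "+" + kind
        if "step_provenance" in out.columns else kind)
    out["offset_used"] = mu

    grouping = list(fits[0].grouping)
    resid = pd.DataFrame({"pre": pre})
    for c in grouping:
        resid[c] = table[c].to_numpy()
    summary = (resid.groupby(grouping)["pre"]
               .agg(["min", "mean", "max", "size"])
               .rename(columns={"size": "n"})
               .reset_index())
    report = NormalizationReport(
        fits=fits, offset_used=mu, steps=[kind], residual_summary=summary)
    return out, report


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_light_model(table, lights, grouping=DEFAULT_GROUPING, window=None,
                    fit_on="second", min_group_size=3):
    """Per-group OLS of activity on well light intensity; see
    :class:`LightIntensityNormalizer`."""
    est = LightIntensityNormalizer(
        light_map=lights, grouping=tuple(grouping), window=window,
        fit_on=fit_on, min_group_size=min_group_size, offset=0.0).fit(table)
    return est.fits_


def fit_batch_model(table, grouping=DEFAULT_GROUPING, window=None,
                    fit_on="second"):
    """Per-group sum-to-zero batch-effect model; see
    :class:`BatchEffectNormalizer`."""
    est = BatchEffectNormalizer(
        grouping=tuple(grouping), window=window, fit_on=fit_on,
        offset=0.0).fit(table)
    return est.fits_


def compute_baseline_target(table, baseline_window=DEFAULT_BASELINE_WINDOW):
    """Grand mean activity over the baseline window, across all groups."""
    base = subset_window(table, *baseline_window)
    if base.empty:
        raise NormalizationError(
            f"no records in baseline window {baseline_window}")
    return float(base["activity"].mean())


def fit_baseline_factors(table, target, grouping=DEFAULT_GROUPING,
                         baseline_window=DEFAULT_BASELINE_WINDOW):
    """Per-group baseline factors (group baseline mean minus target)."""
    est = BaselineNormalizer(
        target=target, baseline_window=baseline_window,
        grouping=tuple(grouping), offset=0.0).fit(table)
    return est.fits_


def integrated_normalize(table, lights, grouping=DEFAULT_GROUPING,
                         window=None, baseline_window=DEFAULT_BASELINE_WINDOW,
                         target=None, fit_on="second", min_group_size=3,
                         offset=0.06):
    """Fit and apply the three-step chain on one table; see
    :class:`IntegratedNormalizer`."""
    est = IntegratedNormalizer(
        light_map=lights, grouping=tuple(grouping), window=window,
        baseline_window=baseline_window, target=target, fit_on=fit_on,
        min_group_size=min_group_size, offset=offset).fit(table)
    return est.transform(table), est.report_


# ---------------------------------------------------------------------------
# GroupFit serialization (CSV-friendly long format)


def fits_to_frame(fits: Iterable[GroupFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        for name in f.coefficients:
            row = dict(zip(f.grouping, f.group))
            row.update(kind=f.kind, term=name,
                       estimate=f.coefficients[name],
                       std_error=f.standard_errors[name],
                       p_value=f.p_values[name],
                       n_obs=f.n_obs)
            rows.append(row)
    return pd.DataFrame(rows)


def fits_from_frame(df: pd.DataFrame) -> list[GroupFit]:
    meta = ["kind", "term", "estimate", "std_error", "p_value", "n_obs"]
    grouping = tuple(c for c in df.columns if c not in meta)
    fits = []
    for (kind, *key), sub in df.groupby(["kind"] + list(grouping), sort=True):
        fits.append(GroupFit(
            tuple(key), grouping, kind,
            dict(zip(sub["term"], sub["estimate"].astype(float))),
            dict(zip(sub["term"], sub["std_error"].astype(float))),
            dict(zip(sub["term"], sub["p_value"].astype(float))),
            int(sub["n_obs"].iloc[0])))
    return fits
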