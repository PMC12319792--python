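"""Vertex-wise linear mixed-effects analysis of longitudinal cortical
thickness and the normative Z-score / AUC diagnostic procedure.

The per-vertex model is

    CTh_ij = b0 + b1 * B_i + b2 * W_ij + b3 * D_i + u0_i + u1_i * W_ij + e_ij

with baseline age ``B_i``, time from the initial visit ``W_ij`` (years), stable
diagnosis ``D_i`` in {0, 1}, per-subject random intercept ``u0_i`` and slope
``u1_i`` (unstructured 2x2 covariance), and the diagnosis effect ``b3`` as the
coefficient of interest.  P-values are uncorrected two-tailed Wald tests; an
optional Benjamini-Hochberg FDR flag is provided but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SubjectRecord:
    """Covariates and per-visit thickness fields of one subject."""

    subject_id: str
    baseline_age: float
    visit_times: np.ndarray          # W_ij, years; W_i0 == 0
    thickness: np.ndarray            # (n_visits, V)
    diagnosis: int                   # stable within subject

    def __post_init__(self) -> None:
        self.visit_times = np.asarray(self.visit_times, dtype=np.float64)
        self.thickness = np.atleast_2d(np.asarray(self.thickness, dtype=np.float64))
        if abs(self.visit_times[0]) > 1e-9:
            raise ValueError("the initial visit must be at time 0")
        if len(self.visit_times) != len(self.thickness):
            raise ValueError("visit_times and thickness rows must align")


def simulate_mixed_model_records(n_subjects: int = 30, n_vertices: int = 8,
                                 beta=(2.5, -0.01, -0.02, -0.3),
                                 re_sd=(0.1, 0.05), noise_sd: float = 0.05,
                                 seed: int | None = 0,
                                 n_visits=(2, 5)) -> list:
    """Thickness records generated exactly from the longitudinal mixed model
    (useful as a calibration oracle: with ``re_sd=(0, 0)`` and ``noise_sd=0``
    any consistent estimator must recover ``beta`` exactly)."""
    rng = np.random.default_rng(seed)
    b0, b1, b2, b3 = beta
    records = []
    for i in range(n_subjects):
        D = i % 2
        B = rng.uniform(60, 85)
        K = int(rng.integers(n_visits[0], n_visits[1] + 1))
        W = np.concatenate([[0.0], np.cumsum(rng.uniform(0.5, 1.5, K - 1))])
        u0 = rng.normal(0, re_sd[0], n_vertices)
        u1 = rng.normal(0, re_sd[1], n_vertices)
        th = (b0 + b1 * B + b3 * D
              + u0[None, :] + (b2 + u1[None, :]) * W[:, None]
              + rng.normal(0, noise_sd, (K, n_vertices)))
        records.append(SubjectRecord(f"s{i:03d}", B, W, th, D))
    return records


def _long_frame(records: list) -> pd.DataFrame:
    rows = []
    for r in records:
        for j, w in enumerate(r.visit_times):
            rows.append({"subject": r.subject_id, "B": r.baseline_age, "W": float(w),
                         "D": int(r.diagnosis), "visit": j})
    return pd.DataFrame(rows)


@dataclass
class LMEResult:
    beta3: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    converged: np.ndarray
    flags: dict = field(default_factory=dict)
    pvalue_fdr: np.ndarray | None = None


def vertexwise_lme(records: list, vertex_mask: np.ndarray | None = None,
                   fdr: bool = False) -> LMEResult:
    """Fit the longitudinal mixed model at every unmasked vertex.

    Returns per-vertex diagnosis effect estimates with t-statistics and
    uncorrected two-tailed p-values.  Vertices where the mixed model does not
    converge are flagged (not dropped); a diagonal random-effects covariance is
    tried as a fallback before flagging.  When the data are an exact linear fit
    (zero residual), the coefficient is recovered by least squares and the test
    statistic is reported as infinite.
    """
    if len({r.diagnosis for r in records}) < 2:
        raise ValueError("need both diagnostic groups present")
    if not any(len(r.visit_times) >= 2 for r in records):
        raise ValueError("need at least one subject with >= 2 visits")
    V = records[0].thickness.shape[1]
    mask = np.ones(V, dtype=bool) if vertex_mask is None else np.asarray(vertex_mask, bool)
    frame = _long_frame(records)
    exog = sm.add_constant(frame[["B", "W", "D"]].to_numpy())
    exog_re = np.column_stack([np.ones(len(frame)), frame["W"].to_numpy()])
    groups = frame["subject"].to_numpy()
    y_all = np.vstack([r.thickness for r in records])  # rows align with frame order

    beta3 = np.full(V, np.nan)
    tstat = np.full(V, np.nan)
    pval = np.full(V, np.nan)
    converged = np.zeros(V, dtype=bool)
    flags: dict = {}
    df_resid = len(frame) - 4

    for v in np.where(mask)[0]:
        y = y_all[:, v]
        # exact-fit degenerate case: the model is identified by OLS alone
        ols_beta, res, rank, _ = np.linalg.lstsq(exog, y, rcond=None)
        rss = float(np.sum((y - exog @ ols_beta) ** 2))
        if rss < 1e-18 * max(1.0, float(np.sum(y ** 2))):
            beta3[v] = ols_beta[3]
            tstat[v] = np.inf if ols_beta[3] != 0 else 0.0
            pval[v] = 0.0 if ols_beta[3] != 0 else 1.0
            converged[v] = True
            flags[v] = "exact-fit (zero residual): OLS coefficients"
            continue
        fit = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for free in (None, "diag"):
                try:
                    model = sm.MixedLM(y, exog, groups=groups, exog_re=exog_re)
                    if free == "diag":
                        fr = sm.regression.mixed_linear_model.MixedLMParams.from_components(
                            fe_params=np.zeros(4), cov_re=np.eye(2))
                        fit = model.fit(free=fr, reml=True, method="lbfgs", maxiter=200)
                    else:
                        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    flags[v] = f"singular fit: {exc}"
                    fit = None
                    continue
                if fit is not None and fit.converged:
                    if free == "diag":
                        flags[v] = "diagonal random-effects fallback"
                    break
        if fit is None:
            continue
        beta3[v] = fit.fe_params[3]
        se = fit.bse_fe[3]
        tstat[v] = beta3[v] / se if se > 0 else np.nan
        pval[v] = 2.0 * stats.t.sf(abs(tstat[v]), df_resid) if se > 0 else np.nan
        converged[v] = bool(fit.converged)
        if not fit.converged:
            flags[v] = flags.get(v, "non-converged mixed fit")

    out = LMEResult(beta3, tstat, pval, converged, flags)
    if fdr:
        p = np.where(np.isnan(pval), 1.0, pval)
        out.pvalue_fdr = multipletests(p, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Normative Z-scores and AUC
# ---------------------------------------------------------------------------

def normative_zscores(records: list, vertex_mask: np.ndarray | None = None,
                      bracket_years: float = 10.0,
                      on_missing_bracket: str = "error") -> pd.DataFrame:
    """Per-scan mean normative Z-score of cortical thickness.

    Reference mean/SD per vertex are estimated per ``bracket_years`` age
    bracket from the *initial scans of control subjects only* (avoiding bias
    toward subjects with many visits); every scan — control and disease, all
    visits — is then scored as the mean Z over unmasked vertices, with the
    bracket chosen by age at scan.  A scan falling in a bracket without at
    least two reference subjects raises an error naming the bracket
    (``on_missing_bracket="nearest"`` scores it against the nearest populated
    bracket instead).
    """
    V = records[0].thickness.shape[1]
    mask = np.ones(V, dtype=bool) if vertex_mask is None else np.asarray(vertex_mask, bool)

    def bracket_of(age):
        return int(np.floor(age / bracket_years))

    ref: dict = {}
    for r in records:
        if r.diagnosis == 0:
            ref.setdefault(bracket_of(r.baseline_age), []).append(r.thickness[0])
    stats_by_bracket = {}
    for b, arrs in ref.items():
        if len(arrs) < 2:
            continue
        arr = np.stack(arrs)
        stats_by_bracket[b] = (arr.mean(axis=0), arr.std(axis=0, ddof=1))

    rows = []
    for r in records:
        for j, w in enumerate(r.visit_times):
            b = bracket_of(r.baseline_age + w)
            if b not in stats_by_bracket:
                lo, hi = b * bracket_years, (b + 1) * bracket_years
                if on_missing_bracket != "nearest" or not stats_by_bracket:
                    raise ValueError(
                        f"age bracket [{lo:g}, {hi:g}) has fewer than 2 reference subjects")
                b = min(sorted(stats_by_bracket), key=lambda a: abs(a - b))
            mu, sd = stats_by_bracket[b]
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (r.thickness[j] - mu) / np.where(sd > 0, sd, np.nan)
            rows.append({"subject_id": r.subject_id, "visit": j,
                         "diagnosis": r.diagnosis,
                         "mean_z": float(np.nanmean(z[mask]))})
    return pd.DataFrame(rows)


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic, midranks
    for ties: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))
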