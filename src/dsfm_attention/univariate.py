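"""Univariate analysis: high-pass filtering, GLM, %BOLD per ROI, ROI statistics.

The four active conditions (attend left/right x same/different rotation) are
modeled as separate explanatory variables, convolved with the gamma
hemodynamic response function; temporal derivatives (orthogonalized against
the rest of the design, so condition betas are unchanged on latency-matched
data) absorb latency differences; a linear drift regressor and optional
confound regressors complete the per-scan design.  The passive static-dots
condition is left out of the design and therefore forms the implicit
baseline of every contrast.

%BOLD amplitudes are condition betas scaled by the per-voxel GLM intercept
(the baseline-intensity estimate), averaged over ROI voxels.  ROI-level
inference uses non-parametric Wilcoxon tests (signed-rank versus zero,
matched-pairs between conditions) with Bonferroni correction over the seven
visual areas, alongside a Kolmogorov-Smirnov normality screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .bold import BoldDataset, RoiSpec, contralateral_side, hrf_kernel
from .design import ACTIVE_CONDITIONS

log = logging.getLogger("dsfm_attention")

__all__ = [
    "GlmFit",
    "highpass",
    "build_design_matrix",
    "fit_glm",
    "roi_percent_bold",
    "condition_amplitudes",
    "condition_table",
    "recover_gains",
    "roi_stats",
]


def highpass(ts: np.ndarray, cutoff: float, tr: float,
             method: str = "gaussian") -> np.ndarray:
    """Remove fluctuations slower than ``cutoff`` seconds (last axis = time).

    method="gaussian" (default) subtracts a Gaussian-weighted running mean
    with sigma = cutoff/2, whose gentle roll-off leaves block-frequency
    signal essentially untouched; method="dct" projects out the
    discrete-cosine components with period longer than the cutoff (a sharp
    spectral cut, but with more leakage near the cutoff).  The temporal
    mean is preserved by both.
    """
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[-1]
    if cutoff <= 2.0 * tr:
        raise ValueError("cutoff must exceed twice the TR")
    if method == "dct":
        duration = T * tr
        K = int(np.floor(2.0 * duration / cutoff))
        if K < 1:
            return ts.copy()
        t = np.arange(T)
        basis = np.stack([np.cos(np.pi * k * (2 * t + 1) / (2 * T))
                          for k in range(1, K + 1)], axis=1)  # (T, K)
        basis /= np.linalg.norm(basis, axis=0)
        flat = ts.reshape(-1, T)
        out = flat - (flat @ basis) @ basis.T  # DCT columns are zero-mean
        return out.reshape(ts.shape)
    if method == "gaussian":
        sigma = (cutoff / 2.0) / tr
        mean = ts.mean(axis=-1, keepdims=True)
        smooth = ndimage.gaussian_filter1d(ts, sigma=sigma, axis=-1,
                                           mode="reflect")
        return ts - smooth + mean
    raise ValueError(f"unknown method {method!r}")


@dataclass
class GlmFit:
    """Per-voxel OLS fit of one scan."""

    design: pd.DataFrame        # (T, p) design matrix
    betas: np.ndarray           # (n_vox, p)
    se: np.ndarray              # (n_vox, p) per-regressor standard errors
    residuals: np.ndarray       # (n_vox, T)
    condition_columns: list[str]
    ar1_rho: float | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.design.columns)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        col = X[:, j]
        if np.allclose(col, 0.0):
            bad.append(names[j])
            continue
        resid = col - others @ np.linalg.lstsq(others, col, rcond=None)[0]
        if np.linalg.norm(resid) < 1e-10 * max(np.linalg.norm(col), 1.0):
            bad.append(names[j])
    return bad


def build_design_matrix(events: pd.DataFrame, scan: int, n_volumes: int,
                        tr: float, derivatives: bool = True,
                        drift: bool = True,
                        confounds: np.ndarray | None = None,
                        hrf_delay: float = 6.0,
                        hrf_sd: float = 3.0) -> pd.DataFrame:
    """HRF-convolved condition regressors (+ derivatives, drift, intercept)."""
    ev = events[events["scan"] == scan]
    kernel = hrf_kernel(hrf_delay, hrf_sd, dt=tr)
    cols: dict[str, np.ndarray] = {}
    for cond in ACTIVE_CONDITIONS:
        box = np.zeros(n_volumes)
        box[ev.loc[ev["condition"] == cond, "volume"].to_numpy(dtype=int)] = 1.0
        cols[cond] = np.convolve(box, kernel)[:n_volumes]
    base = dict(cols)
    if drift:
        base["drift"] = np.linspace(-0.5, 0.5, n_volumes)
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] == n_volumes:
            confounds = confounds.T
        for i, c in enumerate(confounds):
            base[f"confound_{i}"] = c
    base["intercept"] = np.ones(n_volumes)
    if derivatives:
        Xb = np.column_stack(list(base.values()))
        deriv = {}
        for cond in ACTIVE_CONDITIONS:
            d = np.gradient(cols[cond])
            d = d - Xb @ np.linalg.lstsq(Xb, d, rcond=None)[0]
            deriv[f"{cond}_deriv"] = d
        # orthogonalized derivatives do not change the other betas
        out = dict(base)
        out.update(deriv)
    else:
        out = base
    X = pd.DataFrame(out)
    bad = _collinear_columns(X.to_numpy(), list(X.columns))
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear or "
                         f"all-zero columns: {bad}")
    return X


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of Y (T, n) on X (T, p); returns betas, se, residuals (n, ...)."""
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    dof = max(X.shape[0] - X.shape[1], 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    se = np.sqrt(np.outer(sigma2, xtx_inv_diag))
    return betas.T, se, resid.T


def fit_glm(dataset: BoldDataset, scan: int,
            confounds: np.ndarray | None = None,
            derivatives: bool = True, drift: bool = True,
            highpass_cutoff: float | None = None,
            prewhiten: bool = False) -> GlmFit:
    """OLS GLM of one scan across all grid voxels.

    ``highpass_cutoff`` (seconds) filters the data and the condition
    regressors identically before fitting.  ``prewhiten`` applies a global
    AR(1) transform estimated from the pooled OLS residuals and refits (a
    light-weight temporal-autocorrelation correction).
    """
    p = dataset.ground_truth.get("params", {})
    X = build_design_matrix(dataset.events, scan, dataset.volumes_per_scan,
                            dataset.tr, derivatives=derivatives, drift=drift,
                            confounds=confounds,
                            hrf_delay=p.get("hrf_delay", 6.0),
                            hrf_sd=p.get("hrf_sd", 3.0))
    Y = (dataset.data.reshape(-1, dataset.data.shape[-1])
         [:, dataset.scan_slice(scan)].T.astype(float))  # (T, n_vox)
    Xm = X.to_numpy().copy()
    if highpass_cutoff is not None:
        Y = highpass(Y.T, highpass_cutoff, dataset.tr).T
        cond_idx = [X.columns.get_loc(c) for c in ACTIVE_CONDITIONS]
        Xm[:, cond_idx] = highpass(Xm[:, cond_idx].T, highpass_cutoff,
                                   dataset.tr).T
    betas, se, resid = _ols(Xm, Y)
    rho = None
    if prewhiten:
        r = resid
        rho = float(np.sum(r[:, 1:] * r[:, :-1]) / np.sum(r[:, :-1] ** 2))
        rho = float(np.clip(rho, -0.95, 0.95))
        W = np.eye(Xm.shape[0])
        W -= rho * np.eye(Xm.shape[0], k=-1)
        W[0, 0] = np.sqrt(1.0 - rho ** 2)
        betas, se, resid = _ols(W @ Xm, W @ Y)
    return GlmFit(design=X, betas=betas, se=se, residuals=resid,
                  condition_columns=list(ACTIVE_CONDITIONS), ar1_rho=rho)


def roi_percent_bold(dataset: BoldDataset, fit: GlmFit,
                     roi: RoiSpec) -> dict[str, float]:
    """Per-condition %BOLD change of one ROI, relative to the passive baseline.

    Condition betas are scaled by the per-voxel intercept (baseline
    intensity estimate) and averaged over ROI voxels; the passive condition
    is the GLM's implicit baseline and is 0 by construction.
    """
    if roi.n_voxels == 0:
        raise ValueError(f"ROI {roi.name} ({roi.hemisphere}) has an empty mask")
    idx = np.asarray(roi.indices)
    i0 = fit.columns.index("intercept")
    intercept = fit.betas[idx, i0]
    out = {}
    for cond in fit.condition_columns:
        j = fit.columns.index(cond)
        out[cond] = float(np.mean(100.0 * fit.betas[idx, j] / intercept))
    return out


def condition_amplitudes(dataset: BoldDataset, **glm_kwargs) -> pd.DataFrame:
    """%BOLD per (ROI, hemisphere, scan, condition) across all scans."""
    rows = []
    for scan in range(dataset.n_scans):
        fit = fit_glm(dataset, scan, **glm_kwargs)
        for roi in dataset.rois:
            pct = roi_percent_bold(dataset, fit, roi)
            for cond, val in pct.items():
                rows.append({"roi": roi.name, "hemisphere": roi.hemisphere,
                             "scan": scan, "condition": cond, "pct_bold": val})
    return pd.DataFrame(rows)


def condition_table(dataset: BoldDataset, pool: str = "scan",
                    amplitudes: pd.DataFrame | None = None,
                    **glm_kwargs) -> pd.DataFrame:
    """Replicate-level contrast table per visual area.

    For each hemisphere the contralateral cylinder is "attended" on trials
    cued to the opposite visual field; hemispheres are averaged so each
    replicate contributes one row per area with columns ``attended``,
    ``unattended``, ``unattended_same`` and ``unattended_different``.
    ``pool="scan"`` keeps one replicate per scan; ``pool="session"``
    averages consecutive pairs of scans (two scans per session).
    """
    amp = amplitudes if amplitudes is not None else condition_amplitudes(
        dataset, **glm_kwargs)
    rows = []
    for (roi_name, scan), grp in amp.groupby(["roi", "scan"]):
        rec = {"roi": roi_name, "replicate": scan,
               "attended": 0.0, "unattended": 0.0,
               "unattended_same": 0.0, "unattended_different": 0.0}
        for hemi in ("left", "right"):
            g = grp[grp["hemisphere"] == hemi].set_index("condition")["pct_bold"]
            contra = contralateral_side(hemi)
            ipsi = "left" if contra == "right" else "right"
            rec["attended"] += (g[f"attend_{contra}_same"]
                                + g[f"attend_{contra}_different"]) / 2.0
            rec["unattended"] += (g[f"attend_{ipsi}_same"]
                                  + g[f"attend_{ipsi}_different"]) / 2.0
            rec["unattended_same"] += g[f"attend_{ipsi}_same"]
            rec["unattended_different"] += g[f"attend_{ipsi}_different"]
        for k in ("attended", "unattended", "unattended_same",
                  "unattended_different"):
            rec[k] /= 2.0
        rows.append(rec)
    table = pd.DataFrame(rows)
    if pool == "session":
        table["replicate"] = table["replicate"] // 2
        table = (table.groupby(["roi", "replicate"], as_index=False)
                 .mean(numeric_only=True))
    elif pool != "scan":
        raise ValueError(f"unknown pooling {pool!r}")
    return table


def recover_gains(dataset: BoldDataset, amplitudes: pd.DataFrame | None = None,
                  **glm_kwargs) -> dict[str, float]:
    """Least-squares recovery of (g_stim, g_att, g_feat) from %BOLD amplitudes.

    Each (area, hemisphere, scan, condition) amplitude has expectation
    ``g_stim + g_att*[contra attended] + g_feat*[contra unattended & same]``,
    so stacking all cells and solving the 3-parameter regression returns
    unbiased estimates of the generating gains.
    """
    amp = amplitudes if amplitudes is not None else condition_amplitudes(
        dataset, **glm_kwargs)
    rows, y = [], []
    for r in amp.itertuples():
        contra = contralateral_side(r.hemisphere)
        attended = r.condition.startswith(f"attend_{contra}")
        same_unatt = (not attended) and r.condition.endswith("_same")
        rows.append([1.0, 1.0 if attended else 0.0, 1.0 if same_unatt else 0.0])
        y.append(r.pct_bold)
    coef, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(y), rcond=None)
    return {"g_stim": float(coef[0]), "g_att": float(coef[1]),
            "g_feat": float(coef[2])}


def _wilcoxon(x: np.ndarray, y: np.ndarray | None = None) -> tuple[float, float]:
    d = x - y if y is not None else x
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    res = stats.wilcoxon(d)
    return float(res.statistic), float(res.pvalue)


def roi_stats(table: pd.DataFrame, alpha: float = 0.05,
              n_areas: int = 7) -> pd.DataFrame:
    """ROI-level non-parametric tests with Bonferroni correction.

    Per area: signed-rank tests of attended and unattended activation
    against zero, matched-pairs attended vs unattended (spatial attention)
    and unattended same vs different rotation (global feature attention).
    Alpha is divided by ``n_areas``; a Kolmogorov-Smirnov normality p-value
    for the tested sample is reported alongside.
    """
    needed = {"attended", "unattended", "unattended_same",
              "unattended_different"}
    if not needed <= set(table.columns):
        raise ValueError("table must come from condition_table()")
    log.info("Bonferroni correction factor %d applied at alpha=%g",
             n_areas, alpha)
    out = []
    for roi_name, grp in table.groupby("roi"):
        n = len(grp)
        if n < 5:
            raise ValueError(f"need >= 5 paired replicates, got {n} for {roi_name}")
        att = grp["attended"].to_numpy()
        unatt = grp["unattended"].to_numpy()
        us = grp["unattended_same"].to_numpy()
        ud = grp["unattended_different"].to_numpy()
        tests = {
            "attended_vs_zero": (att, None),
            "unattended_vs_zero": (unatt, None),
            "attended_vs_unattended": (att, unatt),
            "same_vs_different_unattended": (us, ud),
        }
        for name, (x, y) in tests.items():
            statv, p = _wilcoxon(x, y)
            d = x - y if y is not None else x
            sd = d.std(ddof=1)
            ks_p = (stats.kstest((d - d.mean()) / sd, "norm").pvalue
                    if sd > 0 else 1.0)
            p_corr = min(1.0, p * n_areas)
            out.append({"roi": roi_name, "test": name, "n": n,
                        "statistic": statv, "p": p, "p_corrected": p_corr,
                        "significant": bool(p_corr < alpha),
                        "ks_normality_p": float(ks_p)})
    return pd.DataFrame(out)
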