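"""Test-retest and intersubject reliability statistics on subject panels.

All statistics operate per region (and per metric) on a SubjectPanel:
test-retest coefficient of variation, a hybrid absolute-agreement ICC
whose within-measurement variance comes from the retest panel and whose
between-subject variance comes from the full cohort, the measurement-
error-corrected intersubject CoV, and the hemispheric laterality index.
Sample (n-1) standard deviations are used throughout.
"""

from __future__ import annotations

import warnings

import numpy as np

from .synthetic_cortex import ParcelGeometry, RegionMap, SubjectPanel

__all__ = [
    "test_retest_cov",
    "icc_absolute",
    "intersubject_cov",
    "laterality_index",
]


def _metric_slice(panel: SubjectPanel, metric: str | int | None) -> np.ndarray:
    """(subject, session, region) values for one metric."""
    if metric is None:
        if panel.values.shape[3] != 1:
            raise ValueError("panel has several metrics; name one")
        return panel.values[..., 0]
    if isinstance(metric, str):
        metric = panel.metric_index(metric)
    return panel.values[..., metric]


def test_retest_cov(panel: SubjectPanel, metric: str | int | None = None) -> RegionMap:
    """Subject-average session SD divided by the grand mean, in percent."""
    x = _metric_slice(panel, metric)
    if x.shape[1] < 2:
        raise ValueError("test_retest_cov needs >= 2 sessions")
    per_subject_sd = x.std(axis=1, ddof=1)  # (subject, region)
    grand_mean = x.mean(axis=(0, 1))  # (region,)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = 100.0 * per_subject_sd.mean(axis=0) / grand_mean
    if not np.isfinite(cov).all():
        warnings.warn("test_retest_cov: zero grand mean in some regions",
                      RuntimeWarning, stacklevel=2)
    return RegionMap(cov, "cov_tr")


def _variance_components(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(sigma_b^2, sigma_w^2, sigma_session^2) per region from a retest table.

    Two-way crossed model value(s, k, r) = mu + subject + session + error,
    estimated by method of moments per region.
    """
    n_sub, n_ses, _ = x.shape
    subj_means = x.mean(axis=1)  # (subject, region)
    sess_means = x.mean(axis=0)  # (session, region)
    grand = x.mean(axis=(0, 1))
    # Residual (error) variance from the interaction term.
    resid = x - subj_means[:, None, :] - sess_means[None, :, :] + grand[None, None, :]
    if n_sub > 1 and n_ses > 1:
        sigma_e2 = (resid**2).sum(axis=(0, 1)) / ((n_sub - 1) * (n_ses - 1))
    else:
        sigma_e2 = np.zeros(x.shape[2])
    sigma_s2 = np.clip(sess_means.var(axis=0, ddof=1) - sigma_e2 / n_sub, 0.0, None) \
        if n_ses > 1 else np.zeros(x.shape[2])
    sigma_b2 = np.clip(subj_means.var(axis=0, ddof=1) - sigma_e2 / n_ses, 0.0, None)
    return sigma_b2, sigma_e2, sigma_s2


def icc_absolute(
    retest_panel: SubjectPanel,
    full_panel: SubjectPanel | None = None,
    metric: str | int | None = None,
) -> RegionMap:
    """Hybrid absolute-agreement ICC per region.

    Within-measurement and session variance come from the retest panel;
    between-subject variance comes from the full cohort (subject means
    corrected for measurement error).  Combined as
    sigma_b^2 / (sigma_b^2 + sigma_w^2 + sigma_session^2), the
    variance-component plug-in form of the two-way mixed single-measures
    absolute-agreement ICC.
    """
    xr = _metric_slice(retest_panel, metric)
    if xr.shape[1] < 2:
        raise ValueError("icc_absolute needs >= 2 retest sessions")
    _, sigma_e2, sigma_s2 = _variance_components(xr)

    if full_panel is None:
        sigma_b2, _, _ = _variance_components(xr)
    else:
        xf = _metric_slice(full_panel, metric)
        n_ses_full = xf.shape[1]
        subj_means = xf.mean(axis=1)
        sigma_b2 = np.clip(
            subj_means.var(axis=0, ddof=1) - sigma_e2 / n_ses_full, 0.0, None
        )

    denom = sigma_b2 + sigma_e2 + sigma_s2
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = sigma_b2 / denom
    if (denom == 0).any():
        warnings.warn("icc_absolute: degenerate variances in some regions",
                      RuntimeWarning, stacklevel=2)
    return RegionMap(icc, "icc")


def intersubject_cov(
    full_panel: SubjectPanel,
    cov_within: RegionMap | None = None,
    metric: str | int | None = None,
) -> RegionMap:
    """Measurement-error-corrected intersubject CoV in percent.

    corrected = sqrt(max(CoV_total^2 - CoV_within^2, 0)), where CoV_total
    is the between-subject SD of subject means over the grand mean.
    """
    x = _metric_slice(full_panel, metric)
    subj_means = x.mean(axis=1)
    grand = x.mean(axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        cov_total = 100.0 * subj_means.std(axis=0, ddof=1) / grand
    if cov_within is None:
        return RegionMap(cov_total, "cov_inter")
    cw = cov_within.values
    if (cw > np.abs(cov_total)).any():
        warnings.warn(
            "intersubject_cov: within-CoV exceeds total CoV in some regions (floored)",
            RuntimeWarning, stacklevel=2,
        )
    corrected = np.sqrt(np.clip(cov_total**2 - cw**2, 0.0, None))
    return RegionMap(corrected, "cov_inter")


def laterality_index(map_: RegionMap, geom: ParcelGeometry) -> RegionMap:
    """LI = (x_LH - x_RH) / (x_LH + x_RH) per homologous pair.

    Returned as a full-length region map: the LI value is stored on the
    left parcel of each pair (and its negation on the right parcel).
    """
    if geom.homologue is None:
        raise ValueError("laterality_index requires a homologue map")
    x = map_.values
    xh = x[geom.homologue]
    denom = x + xh
    with np.errstate(divide="ignore", invalid="ignore"):
        li = np.where(denom == 0, np.nan, (x - xh) / denom)
    if (denom == 0).any():
        warnings.warn("laterality_index: zero pair sum in some regions",
                      RuntimeWarning, stacklevel=2)
    return RegionMap(li, "li")
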