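"""Task partial least squares with permutation and bootstrap inference.

Task PLS decomposes the condition structure of a feature matrix (ERP
voltages per channel x timepoint, or entropy per channel x scale) in one
step: subject rows are averaged within condition, the condition-mean
matrix is column-wise grand-mean centered across conditions, and its SVD
yields latent variables (LVs).  Each LV pairs a condition contrast
(design saliences), a feature weighting (feature saliences) and a
singular value; LVs are ordered by covariance explained s_k^2 / sum s^2.

Inference follows the standard two-level scheme: LV significance by
permuting condition labels within each subject (order of subjects fixed)
and comparing singular values; salience stability by resampling subjects
with replacement (each subject's full condition set kept intact),
re-fitting, aligning each resample's LVs to the original solution by
orthogonal Procrustes rotation of the design-salience space, and forming
bootstrap ratios = original salience / SD of its bootstrap distribution.
|bootstrap ratio| >= 2 is read as roughly 95% confidence of stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

__all__ = [
    "PlsInput",
    "PlsLatentVariable",
    "PlsResult",
    "bootstrap_stability",
    "extract_stable_windows",
    "fit_task_pls",
    "permutation_test",
    "run_task_pls",
]


@dataclass
class PlsInput:
    """Stacked data for one task-PLS analysis.

    ``data`` has subjects nested within conditions (condition-major:
    rows [cond 1 subj 1..n, cond 2 subj 1..n, ...]) and one column per
    feature.  ``feature_index`` maps columns to (channel, position) where
    position is a time in ms (ERP) or a scale window in ms (MSE).
    """

    data: np.ndarray
    n_subjects: int
    n_conditions: int
    condition_labels: tuple = ()
    feature_index: pd.DataFrame | None = None   # columns: channel, position

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D")
        if self.data.shape[0] != self.n_subjects * self.n_conditions:
            raise ValueError("row count must equal n_subjects * n_conditions")
        if np.isnan(self.data).any():
            raise ValueError(
                "data contains missing values; drop or impute undefined "
                "columns first (see from_stack(drop_nan_columns=True))")
        if not self.condition_labels:
            self.condition_labels = tuple(range(1, self.n_conditions + 1))

    @classmethod
    def from_stack(cls, stack: np.ndarray, condition_labels=(),
                   feature_index: pd.DataFrame | None = None,
                   drop_nan_columns: bool = False) -> "PlsInput":
        """Build from a (n_conditions, n_subjects, n_features) array.

        With ``drop_nan_columns`` any feature column containing a missing
        value (e.g. an undefined coarse-scale entropy cell) is removed,
        with the count recorded in ``n_dropped_columns``.
        """
        stack = np.asarray(stack, dtype=float)
        nc, ns, nf = stack.shape
        data = stack.reshape(nc * ns, nf)
        dropped = 0
        if drop_nan_columns:
            ok = ~np.isnan(data).any(axis=0)
            dropped = int((~ok).sum())
            data = data[:, ok]
            if feature_index is not None:
                feature_index = feature_index.loc[ok].reset_index(drop=True)
        inp = cls(data=data, n_subjects=ns, n_conditions=nc,
                  condition_labels=tuple(condition_labels) or (),
                  feature_index=feature_index)
        inp.n_dropped_columns = dropped
        return inp

    def stacked(self) -> np.ndarray:
        return self.data.reshape(self.n_conditions, self.n_subjects, -1)


@dataclass
class PlsLatentVariable:
    design_saliences: np.ndarray      # (n_conditions,), unit norm
    feature_saliences: np.ndarray     # (n_features,), unit norm
    singular_value: float
    covariance_explained: float
    perm_p: float | None = None
    bootstrap_ratios: np.ndarray | None = None


@dataclass
class PlsResult:
    lvs: list[PlsLatentVariable]
    input: PlsInput
    n_perm: int = 0
    n_boot: int = 0
    stable_windows: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lv": np.arange(1, len(self.lvs) + 1),
            "singular_value": [lv.singular_value for lv in self.lvs],
            "covariance_explained": [lv.covariance_explained for lv in self.lvs],
            "perm_p": [lv.perm_p for lv in self.lvs],
        })


def _centered_condition_means(stack: np.ndarray) -> np.ndarray:
    """Condition means (averaging subject rows), grand-mean centered
    column-wise across conditions."""
    m = stack.mean(axis=1)
    return m - m.mean(axis=0, keepdims=True)


def fit_task_pls(inp: PlsInput) -> list[PlsLatentVariable]:
    """SVD of the centered condition-mean matrix; descriptive only.

    Singular values numerically zero (rank deficiency; always at least one
    because centering removes the grand mean) are not reported as LVs.
    Sign convention: the largest-magnitude feature salience of each LV is
    made positive.
    """
    if inp.n_conditions < 2 or inp.n_subjects < 2:
        raise ValueError("need at least 2 conditions and 2 subjects")
    r = _centered_condition_means(inp.stacked())
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    total = float(np.sum(s ** 2))
    tol = max(r.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    lvs: list[PlsLatentVariable] = []
    for k in range(s.size):
        if s[k] <= tol:
            break
        dsal, fsal = u[:, k].copy(), vt[k].copy()
        if fsal[np.argmax(np.abs(fsal))] < 0:
            dsal, fsal = -dsal, -fsal
        lvs.append(PlsLatentVariable(
            design_saliences=dsal, feature_saliences=fsal,
            singular_value=float(s[k]),
            covariance_explained=float(s[k] ** 2 / total)))
    return lvs


def _permuted_singular_values(stack: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    nc, ns, nf = stack.shape
    m = np.zeros((nc, nf))
    for j in range(ns):
        m[rng.permutation(nc)] += stack[:, j, :]
    m /= ns
    return np.linalg.svd(m - m.mean(axis=0, keepdims=True), compute_uv=False)


def permutation_test(inp: PlsInput, lvs: list[PlsLatentVariable],
                     n_perm: int = 500, rng=None) -> np.ndarray:
    """Permutation p per LV: fraction of label-shuffled refits whose k-th
    singular value meets or exceeds the observed one.

    Each permutation independently reassigns the condition labels within
    every subject (subjects stay fixed).  p = count / n_perm, so a planted
    effect exceeded by no permutation reports p = 0.
    """
    if inp.n_conditions < 2:
        raise ValueError("permutation test needs >= 2 conditions")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    stack = inp.stacked()
    obs = np.array([lv.singular_value for lv in lvs])
    counts = np.zeros(len(lvs))
    for _ in range(n_perm):
        s_perm = _permuted_singular_values(stack, rng)
        counts += s_perm[: len(lvs)] >= obs
    p = counts / n_perm
    for lv, pk in zip(lvs, p):
        lv.perm_p = float(pk)
    return p


def bootstrap_stability(inp: PlsInput, lvs: list[PlsLatentVariable],
                        n_boot: int = 500, rng=None) -> np.ndarray:
    """Bootstrap ratios per LV: original feature salience over the SD of
    its distribution across subject resamples.

    Subjects are resampled with replacement, conditions intact; each
    resample is re-fit and its saliences are rotated onto the original
    design-salience basis (orthogonal Procrustes) before pooling, so sign
    and axis flips across resamples do not inflate the SEs.  A feature
    with zero bootstrap SD has ratio 0 if its salience is 0 (no evidence,
    no instability) and NaN otherwise.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if inp.n_subjects < 3:
        raise ValueError("bootstrap needs at least 3 subjects")
    rng = np.random.default_rng(rng)
    stack = inp.stacked()
    k = len(lvs)
    if k == 0:
        return np.zeros((0, inp.data.shape[1]))
    u0 = np.column_stack([lv.design_saliences for lv in lvs])
    v0 = np.column_stack([lv.feature_saliences for lv in lvs])
    boots = np.empty((n_boot, inp.data.shape[1], k))
    for b in range(n_boot):
        idx = rng.integers(0, inp.n_subjects, inp.n_subjects)
        m = stack[:, idx, :].mean(axis=1)
        ub, sb, vbt = np.linalg.svd(m - m.mean(axis=0, keepdims=True),
                                    full_matrices=False)
        rot, _ = orthogonal_procrustes(ub[:, :k], u0)
        boots[b] = vbt[:k].T @ rot
    sd = boots.std(axis=0, ddof=1)                    # (n_features, k)
    ratios = np.empty((k, inp.data.shape[1]))
    for j in range(k):
        with np.errstate(divide="ignore", invalid="ignore"):
            rat = v0[:, j] / sd[:, j]
        rat[(sd[:, j] == 0) & (v0[:, j] == 0)] = 0.0
        rat[(sd[:, j] == 0) & (v0[:, j] != 0)] = np.nan
        ratios[j] = rat
        lvs[j].bootstrap_ratios = rat
    return ratios


def extract_stable_windows(lv: PlsLatentVariable, feature_index: pd.DataFrame,
                           threshold: float = 2.0, min_run_ms: float = 10.0,
                           scale_features: bool = False) -> pd.DataFrame:
    """Maximal contiguous runs of |bootstrap ratio| >= threshold per channel.

    Runs are split where the salience sign changes; each reported window
    carries the sign of its saliences.  For time features a run must span
    at least ``min_run_ms`` (run length x sample spacing); for scale
    features (``scale_features=True``) one scale suffices.

    Returns a frame with columns channel, start, end, n_points, sign.
    """
    if lv.bootstrap_ratios is None:
        raise ValueError("run bootstrap_stability first")
    fi = feature_index
    rows = []
    for ch, grp in fi.groupby("channel", sort=False):
        order = np.argsort(grp["position"].to_numpy())
        pos = grp["position"].to_numpy()[order]
        cols = grp.index.to_numpy()[order]
        bsr = lv.bootstrap_ratios[cols]
        sal = lv.feature_saliences[cols]
        hit = np.abs(bsr) >= threshold
        sign = np.sign(sal)
        dt = np.median(np.diff(pos)) if len(pos) > 1 else 0.0
        i = 0
        while i < len(pos):
            if not hit[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(pos) and hit[j + 1] and sign[j + 1] == sign[i]:
                j += 1
            n_pts = j - i + 1
            duration = n_pts * dt if dt > 0 else float(n_pts)
            if scale_features or dt == 0 or duration >= min_run_ms:
                rows.append((ch, pos[i], pos[j], n_pts, int(sign[i])))
            i = j + 1
    return pd.DataFrame(rows, columns=["channel", "start", "end", "n_points", "sign"])


def run_task_pls(inp: PlsInput, n_perm: int = 500, n_boot: int = 500,
                 rng=None, bsr_threshold: float = 2.0,
                 min_run_ms: float = 10.0, scale_features: bool = False) -> PlsResult:
    """Fit + permutation test + bootstrap + stable windows in one call.

    ``n_perm=0`` / ``n_boot=0`` skip the corresponding inference step
    (descriptive-only mode).  ``rng`` seeds both resampling schemes
    reproducibly (permutations first, then bootstrap, from one stream).
    """
    rng = np.random.default_rng(rng)
    lvs = fit_task_pls(inp)
    if n_perm > 0 and lvs:
        permutation_test(inp, lvs, n_perm=n_perm, rng=rng)
    windows = None
    if n_boot > 0 and lvs:
        bootstrap_stability(inp, lvs, n_boot=n_boot, rng=rng)
        if inp.feature_index is not None:
            frames = []
            for k, lv in enumerate(lvs, start=1):
                w = extract_stable_windows(lv, inp.feature_index,
                                           threshold=bsr_threshold,
                                           min_run_ms=min_run_ms,
                                           scale_features=scale_features)
                w.insert(0, "lv", k)
                if not w.empty:
                    frames.append(w)
            windows = (pd.concat(frames, ignore_index=True) if frames
                       else pd.DataFrame(columns=["lv", "channel", "start",
                                                  "end", "n_points", "sign"]))
    return PlsResult(lvs=lvs, input=inp, n_perm=n_perm, n_boot=n_boot,
                     stable_windows=windows)
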