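"""Partial least squares for brain-group and brain-behavior association.

Two model classes, both decomposing a cross-block matrix by SVD into
latent variables (LVs) — triplets of a feature-side singular vector
("salience"), a singular value, and a group/variable-side singular
vector ("contrast"):

* :class:`MeanCenteredPLS` decomposes the features x groups matrix of
  group means after removing each feature's (unweighted) grand mean
  across groups, testing for group differences in the feature pattern.
* :class:`BehavioralPLS` decomposes the features x variables Pearson
  correlation matrix computed over all included subjects, testing for
  a shared brain-behavior association.

Inference is resampling-based: significance of each LV's singular value
by permutation (group labels, or behavioral rows against the brain
block), and feature reliability by bootstrap resampling of subjects
within group.  The original salience divided by its bootstrap standard
error gives a bootstrap ratio interpreted as a z-score; contrast
elements get percentile confidence intervals.  One p-value per LV means
no multiple-comparison correction over features is required.

Both models follow the statsmodels idiom: construct from data, call
``fit()``, receive a results object with a ``summary()``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BandPowerMatrix
from .errors import ConfigError, DataError

DEFAULT_N_PERM = 500
DEFAULT_N_BOOT = 500
_MAX_REDRAWS = 100


def _as_matrix(X, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ConfigError(f"{name} must be 2-d (subjects x columns)")
    if np.isnan(X).any():
        raise DataError(f"{name} contains missing values; apply listwise deletion first")
    if not np.all(np.isfinite(X)):
        raise DataError(f"{name} contains non-finite values")
    return X


def _group_indices(groups) -> tuple[list[np.ndarray], list]:
    labels = pd.unique(np.asarray(groups))
    idx = [np.flatnonzero(np.asarray(groups) == lab) for lab in labels]
    return idx, list(labels)


def _fix_signs(U: np.ndarray, s: np.ndarray, V: np.ndarray):
    """Per LV, make the largest-|element| contrast entry positive."""
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    return U, s, V


def _zscore_columns(A: np.ndarray, names, what: str) -> np.ndarray:
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        offender = names[bad[0]] if names is not None else f"column {bad[0]}"
        raise DataError(f"constant {what}: {offender} has zero variance")
    return (A - mu) / sd


def mean_centered_decomposition(
    X: np.ndarray, group_idx: list[np.ndarray], weighted: bool = False
):
    """SVD of the grand-mean-centered group-means matrix (features x groups).

    Returns (saliences, singular_values, contrasts) truncated to the
    n_groups - 1 structural LVs; centering makes each feature row sum to
    zero (unweighted) so at most that many are nonzero.
    """
    means = np.stack([X[idx].mean(axis=0) for idx in group_idx], axis=1)  # (p, G)
    if weighted:
        w = np.array([len(idx) for idx in group_idx], dtype=float)
        grand = means @ (w / w.sum())
    else:
        grand = means.mean(axis=1)
    Mc = means - grand[:, None]
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    k = len(group_idx) - 1
    return _fix_signs(U[:, :k].copy(), s[:k].copy(), Vt[:k].T.copy())


def behavioral_decomposition(
    X: np.ndarray,
    Y: np.ndarray,
    feature_names=None,
    variable_names=None,
    group_idx: list[np.ndarray] | None = None,
    within_group: bool = False,
):
    """SVD of the features x variables Pearson correlation matrix.

    By default correlations pool all subjects; ``within_group=True``
    computes per-group correlation matrices and stacks them along the
    variables axis (contrasts then carry one block per group).
    """
    if within_group:
        if not group_idx:
            raise ConfigError("within_group correlation requires group labels")
        blocks = []
        for idx in group_idx:
            Zx = _zscore_columns(X[idx], feature_names, "feature")
            Zy = _zscore_columns(Y[idx], variable_names, "behavioral variable")
            blocks.append(Zx.T @ Zy / len(idx))
        R = np.concatenate(blocks, axis=1)
    else:
        Zx = _zscore_columns(X, feature_names, "feature")
        Zy = _zscore_columns(Y, variable_names, "behavioral variable")
        R = Zx.T @ Zy / X.shape[0]
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    return _fix_signs(U.copy(), s.copy(), Vt.T.copy())


def brain_scores(X: np.ndarray, saliences: np.ndarray) -> np.ndarray:
    """Per-subject projection of the feature matrix onto each salience."""
    X = np.asarray(X, dtype=float)
    saliences = np.asarray(saliences, dtype=float)
    if X.shape[1] != saliences.shape[0]:
        raise ConfigError(
            f"feature dimensions do not match: X has {X.shape[1]}, saliences {saliences.shape[0]}"
        )
    return X @ saliences


class PLSResults:
    """Point estimates plus permutation and bootstrap inference for a PLS fit."""

    def __init__(
        self,
        model,
        singular_values: np.ndarray,
        saliences: np.ndarray,
        contrasts: np.ndarray,
        scores: np.ndarray,
        contrast_labels: list,
        p_values: np.ndarray | None = None,
        bootstrap_ratios: np.ndarray | None = None,
        contrast_cis: np.ndarray | None = None,
        n_perm: int = 0,
        n_boot: int = 0,
        seed: int | None = None,
    ) -> None:
        self.model = model
        self.singular_values = singular_values
        self.saliences = saliences
        self.contrasts = contrasts
        self.brain_scores = scores
        self.contrast_labels = contrast_labels
        self.p_values = p_values
        self.bootstrap_ratios = bootstrap_ratios
        self.contrast_cis = contrast_cis  # (labels, LVs, 2): lower, upper
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.seed = seed

    @property
    def n_lv(self) -> int:
        return len(self.singular_values)

    @property
    def covariance_explained(self) -> np.ndarray:
        """Fraction of squared singular-value energy per LV."""
        s2 = self.singular_values**2
        total = s2.sum()
        return s2 / total if total > 0 else s2

    def zmap(self, lv: int = 0):
        """Bootstrap-ratio map of one LV reshaped to sources x bands."""
        from .posthoc import ZMap

        if self.bootstrap_ratios is None:
            raise DataError("fit with n_boot > 0 to obtain bootstrap-ratio maps")
        fi = self.model.feature_index
        if fi is None:
            raise DataError("model has no (source, band) feature index")
        sources = sorted({s for s, _ in fi})
        bands = list(dict.fromkeys(b for _, b in fi))
        values = self.bootstrap_ratios[:, lv].reshape(len(sources), len(bands))
        return ZMap(values, tuple(bands), provenance=f"{type(self.model).__name__} LV{lv + 1}")

    def summary(self) -> str:
        lines = [f"{type(self.model).__name__} results"]
        lines.append(f"  subjects: {self.model.n_subjects}, features: {self.model.n_features}")
        lines.append(f"  permutations: {self.n_perm}, bootstraps: {self.n_boot}, seed: {self.seed}")
        header = f"  {'LV':>3} {'singular value':>15} {'% cov':>7}"
        if self.p_values is not None:
            header += f" {'perm p':>8}"
        lines.append(header)
        for k in range(self.n_lv):
            row = f"  {k + 1:>3} {self.singular_values[k]:>15.4f} {100 * self.covariance_explained[k]:>6.1f}%"
            if self.p_values is not None:
                row += f" {self.p_values[k]:>8.4f}"
            lines.append(row)
        lines.append("  LV1 contrast:")
        for i, lab in enumerate(self.contrast_labels):
            row = f"    {lab:>12}: {self.contrasts[i, 0]:+.3f}"
            if self.contrast_cis is not None:
                lo, hi = self.contrast_cis[i, 0]
                row += f"  [{lo:+.3f}, {hi:+.3f}]"
            lines.append(row)
        return "\n".join(lines)

    def plot_contrast(self, lv: int = 0, ax=None):
        """Bar chart of one LV's contrast with bootstrap CI whiskers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(self.contrast_labels))
        vals = self.contrasts[:, lv]
        ax.bar(x, vals, color="steelblue")
        if self.contrast_cis is not None:
            err = np.abs(self.contrast_cis[:, lv, :].T - vals)
            ax.errorbar(x, vals, yerr=err, fmt="none", ecolor="k", capsize=3)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_xticks(x)
        ax.set_xticklabels([str(c) for c in self.contrast_labels], rotation=45, ha="right")
        ax.set_ylabel(f"LV{lv + 1} contrast")
        return ax

    def save(self, out_dir) -> None:
        """Write the results as a directory of CSVs plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lv_cols = [f"LV{k + 1}" for k in range(self.n_lv)]
        feat = self.model.feature_names or [f"f{i}" for i in range(self.model.n_features)]
        pd.DataFrame({"singular_value": self.singular_values},
                     index=pd.Index(lv_cols, name="lv")).to_csv(out / "singular_values.csv")
        contr = pd.DataFrame(self.contrasts, index=pd.Index(
            [str(c) for c in self.contrast_labels], name="label"), columns=lv_cols)
        if self.contrast_cis is not None:
            for k, col in enumerate(lv_cols):
                contr[f"{col}_ci_lo"] = self.contrast_cis[:, k, 0]
                contr[f"{col}_ci_hi"] = self.contrast_cis[:, k, 1]
        contr.to_csv(out / "contrasts.csv")
        pd.DataFrame(self.saliences, index=pd.Index(feat, name="feature"),
                     columns=lv_cols).to_csv(out / "saliences.csv")
        if self.bootstrap_ratios is not None:
            pd.DataFrame(self.bootstrap_ratios, index=pd.Index(feat, name="feature"),
                         columns=lv_cols).to_csv(out / "bootstrap_ratios.csv")
        if self.p_values is not None:
            pd.DataFrame({"p_value": self.p_values},
                         index=pd.Index(lv_cols, name="lv")).to_csv(out / "p_values.csv")
        pd.DataFrame(self.brain_scores, columns=lv_cols,
                     index=pd.Index(self.model.subject_ids, name="subject_id")
                     ).to_csv(out / "brain_scores.csv")
        manifest = {
            "model": type(self.model).__name__,
            "n_perm": self.n_perm,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_subjects": self.model.n_subjects,
            "n_features": self.model.n_features,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


class _BasePLS:
    """Shared plumbing: data checks, permutation and bootstrap loops."""

    def __init__(self, X, groups=None, feature_names=None, feature_index=None,
                 subject_ids=None) -> None:
        self.X = _as_matrix(X, "X")
        self.feature_names = list(feature_names) if feature_names is not None else None
        self.feature_index = feature_index
        self.subject_ids = (
            list(subject_ids) if subject_ids is not None
            else [f"sub{i:03d}" for i in range(self.X.shape[0])]
        )
        if groups is not None:
            groups = np.asarray(groups)
            if len(groups) != self.X.shape[0]:
                raise ConfigError("groups length must match the subject axis")
            self.group_idx, self.group_labels = _group_indices(groups)
        else:
            self.group_idx, self.group_labels = None, None

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    # subclasses implement: _decompose(X, Y) -> (U, s, V); _contrast_labels()

    def fit(
        self,
        n_perm: int = DEFAULT_N_PERM,
        n_boot: int = DEFAULT_N_BOOT,
        seed: int | None = None,
        procrustes: bool = False,
    ) -> PLSResults:
        """Point estimates, permutation p-values and bootstrap inference.

        ``n_perm=0`` / ``n_boot=0`` skip the respective resampling stage.
        ``procrustes=True`` rotationally aligns each bootstrap solution
        to the original across LVs instead of per-LV sign flipping.
        """
        if 0 < n_perm < 100:
            warnings.warn(f"n_perm={n_perm} is low; p-value resolution will be coarse", stacklevel=2)
        if 0 < n_boot < 100:
            warnings.warn(f"n_boot={n_boot} is low; bootstrap SEs will be noisy", stacklevel=2)
        rng = np.random.default_rng(seed)
        U, s, V = self._decompose_full()
        scores = brain_scores(self.X, U)
        p_values = self._permutation(s, n_perm, rng) if n_perm > 0 else None
        bsr, cis = (None, None)
        if n_boot > 0:
            bsr, cis = self._bootstrap(U, V, n_boot, rng, procrustes)
        return PLSResults(
            self, s, U, V, scores, self._contrast_labels(),
            p_values=p_values, bootstrap_ratios=bsr, contrast_cis=cis,
            n_perm=n_perm, n_boot=n_boot, seed=seed,
        )

    def _permutation(self, s_obs: np.ndarray, n_perm: int, rng) -> np.ndarray:
        """p(LV k) = (#{perm: s_perm(k) >= s_obs(k)} + 1) / (n_perm + 1)."""
        count = np.zeros_like(s_obs)
        n = self.n_subjects
        for _ in range(n_perm):
            perm = rng.permutation(n)
            _, s_p, _ = self._decompose_permuted(perm)
            count += s_p[: len(s_obs)] >= s_obs
        return (count + 1) / (n_perm + 1)

    def _resample_rows(self, rng) -> np.ndarray:
        """Within-group bootstrap draw; whole-sample if no groups.

        Draws collapsing any group onto a single unique subject are
        redrawn (they make the group mean degenerate)."""
        blocks = self.group_idx if self.group_idx is not None else [np.arange(self.n_subjects)]
        rows = []
        for idx in blocks:
            draw = None
            for _ in range(_MAX_REDRAWS + 1):
                cand = rng.choice(idx, size=len(idx), replace=True)
                if len(idx) == 1 or len(np.unique(cand)) > 1:
                    draw = cand
                    break
            if draw is None:
                raise DataError("bootstrap resampling kept collapsing a group to one subject")
            rows.append(draw)
        return np.concatenate(rows)

    def _bootstrap(self, U, V, n_boot: int, rng, procrustes: bool):
        p, k = U.shape
        boot_u = np.empty((n_boot, p, k))
        boot_v = np.empty((n_boot, V.shape[0], k))
        for b in range(n_boot):
            rows = self._resample_rows(rng)
            Ub, sb, Vb = self._decompose_resampled(rows)
            Ub, Vb = Ub[:, :k], Vb[:, :k]
            if procrustes:
                W1, _, W2t = np.linalg.svd(Ub.T @ U)
                Q = W1 @ W2t
                Ub = Ub @ Q
                Vb = Vb @ Q
            else:
                flip = np.sign(np.einsum("pk,pk->k", Ub, U))
                flip[flip == 0] = 1.0
                Ub = Ub * flip
                Vb = Vb * flip
            boot_u[b] = Ub
            boot_v[b] = Vb
        se = boot_u.std(axis=0, ddof=1)
        # a vanishing SE means the resampled salience is degenerate
        # (e.g. a feature with no variance): the ratio is 0 by
        # convention; the floor absorbs pure rounding noise from
        # bit-identical resamples
        degenerate = se <= 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr = np.where(degenerate, 0.0, U / np.where(degenerate, 1.0, se))
        cis = np.stack(
            [np.percentile(boot_v, 2.5, axis=0), np.percentile(boot_v, 97.5, axis=0)],
            axis=-1,
        )
        return bsr, cis


class MeanCenteredPLS(_BasePLS):
    """Group-contrast PLS on a subjects x features brain matrix.

    Parameters
    ----------
    X : (n_subjects, n_features) relative-power features, no missing values.
    groups : per-subject group labels; at least two groups with n >= 2.
    weighted_centering : remove the group-size-weighted grand mean
        instead of the unweighted mean of group means (default False so
        the contrast is not dominated by the largest group).
    """

    def __init__(self, X, groups, feature_names=None, feature_index=None,
                 subject_ids=None, weighted_centering: bool = False) -> None:
        super().__init__(X, groups=groups, feature_names=feature_names,
                         feature_index=feature_index, subject_ids=subject_ids)
        if self.group_idx is None or len(self.group_idx) < 2:
            raise ConfigError("mean-centered PLS needs at least two groups")
        for idx, lab in zip(self.group_idx, self.group_labels):
            if len(idx) < 2:
                raise DataError(f"group {lab!r} has fewer than 2 subjects")
        self.weighted_centering = weighted_centering
        self._labels = np.empty(self.n_subjects, dtype=int)
        for g, idx in enumerate(self.group_idx):
            self._labels[idx] = g

    @classmethod
    def from_band_power(cls, bpm: BandPowerMatrix, cohort: pd.DataFrame,
                        group_col: str = "group", **kwargs) -> "MeanCenteredPLS":
        groups = cohort.loc[bpm.subject_ids, group_col].to_numpy()
        return cls(bpm.flatten(), groups, feature_names=bpm.feature_names,
                   feature_index=bpm.feature_index, subject_ids=bpm.subject_ids, **kwargs)

    def _contrast_labels(self):
        return self.group_labels

    def _decompose_full(self):
        return mean_centered_decomposition(self.X, self.group_idx, self.weighted_centering)

    def _decompose_permuted(self, perm):
        idx = [perm[g] for g in self.group_idx]
        return mean_centered_decomposition(self.X, idx, self.weighted_centering)

    def _decompose_resampled(self, rows):
        labels = self._labels[rows]
        idx = [np.flatnonzero(labels == g) for g in range(len(self.group_idx))]
        return mean_centered_decomposition(self.X[rows], idx, self.weighted_centering)


class BehavioralPLS(_BasePLS):
    """Brain-behavior PLS on the features x variables correlation matrix.

    Correlations pool all included subjects; ``groups`` (optional) are
    used for within-group bootstrap resampling and, with
    ``within_group_correlation=True``, for the stacked per-group
    correlation variant.
    """

    def __init__(self, X, Y, groups=None, variable_names=None, feature_names=None,
                 feature_index=None, subject_ids=None,
                 within_group_correlation: bool = False) -> None:
        super().__init__(X, groups=groups, feature_names=feature_names,
                         feature_index=feature_index, subject_ids=subject_ids)
        self.Y = _as_matrix(Y, "Y")
        if self.Y.shape[0] != self.X.shape[0]:
            raise ConfigError("X and Y must have aligned subject rows")
        self.variable_names = (
            list(variable_names) if variable_names is not None
            else [f"var{j}" for j in range(self.Y.shape[1])]
        )
        self.within_group_correlation = within_group_correlation
        # fail fast on degenerate columns
        _zscore_columns(self.X, self.feature_names, "feature")
        _zscore_columns(self.Y, self.variable_names, "behavioral variable")

    @classmethod
    def from_band_power(cls, bpm: BandPowerMatrix, cohort: pd.DataFrame,
                        variables: list[str], group_col: str | None = "group",
                        **kwargs) -> "BehavioralPLS":
        """Listwise-delete subjects missing any of ``variables``, align rows."""
        sub = cohort.loc[bpm.subject_ids, variables]
        keep = ~sub.isna().any(axis=1)
        keep_idx = np.flatnonzero(keep.to_numpy())
        if keep_idx.size < 3:
            raise DataError("fewer than 3 complete cases for the requested variables")
        groups = None
        if group_col is not None and group_col in cohort.columns:
            groups = cohort.loc[bpm.subject_ids, group_col].to_numpy()[keep_idx]
        return cls(
            bpm.flatten()[keep_idx], sub.to_numpy()[keep_idx], groups=groups,
            variable_names=variables, feature_names=bpm.feature_names,
            feature_index=bpm.feature_index,
            subject_ids=[bpm.subject_ids[i] for i in keep_idx], **kwargs,
        )

    def _contrast_labels(self):
        if self.within_group_correlation:
            return [f"{lab}:{v}" for lab in self.group_labels for v in self.variable_names]
        return self.variable_names

    def _decompose(self, X, Y, group_idx):
        return behavioral_decomposition(
            X, Y, feature_names=self.feature_names, variable_names=self.variable_names,
            group_idx=group_idx, within_group=self.within_group_correlation,
        )

    def _decompose_full(self):
        return self._decompose(self.X, self.Y, self.group_idx)

    def _decompose_permuted(self, perm):
        return self._decompose(self.X, self.Y[perm], self.group_idx)

    def _decompose_resampled(self, rows):
        if self.group_idx is not None:
            labels = np.empty(self.n_subjects, dtype=int)
            for g, idx in enumerate(self.group_idx):
                labels[idx] = g
            rl = labels[rows]
            gidx = [np.flatnonzero(rl == g) for g in range(len(self.group_idx))]
        else:
            gidx = None
        return self._decompose(self.X[rows], self.Y[rows], gidx)


def permutation_test(model: _BasePLS, n_perm: int = DEFAULT_N_PERM,
                     seed: int | None = None) -> np.ndarray:
    """Permutation p-values per LV without running the bootstrap."""
    res = model.fit(n_perm=n_perm, n_boot=0, seed=seed)
    return res.p_values


def bootstrap_inference(model: _BasePLS, n_boot: int = DEFAULT_N_BOOT,
                        seed: int | None = None):
    """Bootstrap ratios and contrast CIs without running permutations."""
    res = model.fit(n_perm=0, n_boot=n_boot, seed=seed)
    return res.bootstrap_ratios, res.contrast_cis
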