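"""Group spatial ICA of block-design BOLD and network-level statistics.

The decomposition follows the standard group-ICA recipe for fMRI: per-voxel
intensity normalization to percent of the voxel mean, subject-level temporal
PCA, temporal concatenation across subjects, group PCA to the target
component count (20 by convention for whole-brain data), and extended
infomax unmixing of the whitened data into spatially independent maps.
Subject-specific time courses and maps are recovered by dual regression of
the group maps against each subject's data.

Downstream of the decomposition: rule-based artifact screening (rim-mask
mass and motion correlation), network-engagement betas from a multiple
regression of each component time course on HRF-convolved condition
regressors (with motion and the self-paced test phase as nuisance), the
contrasts "listening vs rest" (PL - rest) and "suppressed listening vs
motor+rest baseline" (AS - mean(rest, speech-motor)), group comparisons of
those betas with a 2-SD outlier exclusion, and one-sample t group maps
thresholded by voxel p and cluster extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .behavior import bh_fdr, mann_whitney, wilcoxon_signed
from .synthdata import BoldDataset, condition_regressors, double_gamma_hrf

CONDITIONS = ("rest", "PL", "AS", "speech_motor", "test")


@dataclass
class ICADecomposition:
    group_maps: np.ndarray  # (components, voxels)
    subject_timecourses: list[np.ndarray]  # each (components, time)
    subject_maps: list[np.ndarray]  # each (components, voxels)
    n_components: int
    grid_shape: tuple[int, int, int]
    mask: np.ndarray  # boolean (x, y, z)
    mixing_info: dict = field(default_factory=dict)


@dataclass
class NetworkEngagement:
    betas: np.ndarray  # (subjects, components, contrasts)
    contrast_names: tuple[str, ...]
    excluded: np.ndarray  # boolean, same shape as betas
    condition_betas: np.ndarray  # (subjects, components, len(CONDITIONS))


@dataclass
class GroupMap:
    t_map: np.ndarray  # (x, y, z)
    thresholded_mask: np.ndarray  # boolean
    clusters: list[dict]
    voxel_p: float
    extent: int


# ---------------------------------------------------------------------------
# group spatial ICA


def _percent_normalize(mat: np.ndarray) -> np.ndarray:
    """Scale each voxel's series to percent of its temporal mean, demeaned."""
    mean = mat.mean(axis=0, keepdims=True)
    safe = np.where(np.abs(mean) < 1e-9, 1.0, mean)
    out = 100.0 * mat / safe
    return out - out.mean(axis=0, keepdims=True)


def _pca_reduce(mat: np.ndarray, k: int) -> np.ndarray:
    """Project (time x voxels) data onto its top-k temporal components."""
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    return (s[:k, None] * vt[:k])


def extended_infomax(
    x: np.ndarray,
    seed: int = 0,
    lrate: float | None = None,
    max_epochs: int = 512,
    tol: float = 1e-6,
) -> np.ndarray:
    """Extended infomax ICA unmixing of whitened data ``x`` (comps x samples).

    Natural-gradient updates with sub/super-Gaussian switching via the
    kurtosis sign of each estimated source, learning-rate annealing on
    oscillation, convergence when the relative weight change drops below
    ``tol``.  Returns the unmixing matrix W with sources = W @ x.
    """
    k, n = x.shape
    rng = np.random.default_rng(seed)
    w = np.eye(k) + 0.01 * rng.standard_normal((k, k))
    if lrate is None:
        lrate = 0.01 / np.log(max(k, 2.0))
    block = max(64, int(np.sqrt(n / 3)))
    eye = np.eye(k)
    signs = np.ones(k)
    last_delta = None
    for epoch in range(max_epochs):
        perm = rng.permutation(n)
        w_old = w.copy()
        for start in range(0, n - block + 1, block):
            xb = x[:, perm[start:start + block]]
            u = w @ xb
            y = np.tanh(u)
            grad = (block * eye - (signs[:, None] * y) @ u.T - u @ u.T) / block
            w = w + lrate * grad @ w
            if not np.all(np.isfinite(w)) or np.max(np.abs(w)) > 1e8:
                # blow-up: restart with a smaller rate
                w = np.eye(k) + 0.01 * rng.standard_normal((k, k))
                lrate *= 0.5
                break
        u = w @ x
        # sub/super-Gaussian switching by excess kurtosis of current sources
        m2 = np.mean(u**2, axis=1)
        m4 = np.mean(u**4, axis=1)
        signs = np.sign(m4 / np.maximum(m2**2, 1e-12) - 3.0)
        signs[signs == 0] = 1.0
        delta = np.linalg.norm(w - w_old) / max(np.linalg.norm(w_old), 1e-12)
        if last_delta is not None and delta > 2 * last_delta:
            lrate *= 0.9  # anneal on oscillation
        last_delta = delta
        if delta < tol:
            break
    return w


def group_ica(
    data: BoldDataset,
    n_components: int = 20,
    seed: int = 0,
    subject_dim: int | None = 40,
    mask: np.ndarray | None = None,
) -> ICADecomposition:
    """Two-stage PCA + extended infomax group spatial ICA with dual regression.

    Each subject's (time x voxels) matrix is percent-normalized and reduced
    to ``subject_dim`` temporal dimensions, the reductions are concatenated
    in time and reduced again to ``n_components``, whitened, and unmixed by
    extended infomax into group spatial maps.  Subject time courses and maps
    come from dual regression of the group maps against each subject's
    normalized data.  Component sign is fixed so each map's absolute peak is
    positive, and components are ordered by explained variance.
    """
    if data.n_subjects < 2:
        raise ValueError("group ICA needs at least 2 subjects")
    grid_shape = data.data[0].shape[:3]
    if mask is None:
        mask = data.mask if data.mask is not None else np.ones(grid_shape, bool)
    n_trs = data.data[0].shape[-1]
    if n_components > n_trs:
        raise ValueError(
            f"n_components={n_components} exceeds time points ({n_trs}); "
            "lower the component count"
        )

    subj_norm = []
    reduced = []
    for vol in data.data:
        mat = vol[mask].T  # (time, voxels)
        mat = _percent_normalize(mat)
        subj_norm.append(mat)
        d = min(subject_dim or n_trs, n_trs, mat.shape[1])
        d = max(d, n_components)
        reduced.append(_pca_reduce(mat, d))
    concat = np.vstack(reduced)  # (sum reduced dims, voxels)

    u, s, vt = np.linalg.svd(concat, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0]))
    if rank < n_components:
        raise ValueError(
            f"data rank {rank} below requested {n_components} components; "
            "lower the component count"
        )
    white = vt[:n_components]  # (components, voxels), orthonormal rows
    w = extended_infomax(white * np.sqrt(white.shape[1]), seed=seed)
    maps = w @ white  # (components, voxels)
    # unit-norm maps, sign so the absolute peak is positive
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    peak = maps[np.arange(len(maps)), np.argmax(np.abs(maps), axis=1)]
    maps *= np.sign(peak)[:, None]

    # order by variance explained in the concatenated data
    proj = concat @ maps.T
    order = np.argsort(-np.sum(proj**2, axis=0))
    maps = maps[order]

    timecourses, subject_maps = [], []
    pinv_maps = np.linalg.pinv(maps)
    for mat in subj_norm:
        tc = (mat @ pinv_maps).T  # (components, time): spatial regression
        timecourses.append(tc)
        sm = np.linalg.lstsq(tc.T, mat, rcond=None)[0]  # temporal regression
        subject_maps.append(sm)

    return ICADecomposition(
        group_maps=maps,
        subject_timecourses=timecourses,
        subject_maps=subject_maps,
        n_components=n_components,
        grid_shape=grid_shape,
        mask=mask,
        mixing_info={"unmixing": w, "whitening": white, "seed": seed},
    )


def match_components(
    maps: np.ndarray, true_maps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian assignment of components to reference maps.

    Resolves ICA order/sign ambiguity: components are matched to references
    on absolute spatial correlation and flipped to correlate positively.
    Returns (assignment, signed correlations); ``assignment[j]`` is the
    component index matched to reference j.
    """
    from scipy.optimize import linear_sum_assignment

    k_ref = true_maps.shape[0]
    corr = np.corrcoef(np.vstack([true_maps, maps]))[:k_ref, k_ref:]
    rows, cols = linear_sum_assignment(-np.abs(corr))
    assignment = np.empty(k_ref, int)
    rs = np.empty(k_ref)
    for r, c in zip(rows, cols):
        assignment[r] = c
        rs[r] = corr[r, c]
    return assignment, rs


# ---------------------------------------------------------------------------
# component screening


def rim_mask(grid_shape: tuple[int, int, int], width: int = 1) -> np.ndarray:
    """Boolean mask of the outer rim of the volume (edge/vessel surrogate)."""
    m = np.zeros(grid_shape, bool)
    m[:width], m[-width:] = True, True
    m[:, :width], m[:, -width:] = True, True
    m[:, :, :width], m[:, :, -width:] = True, True
    return m


def screen_components(
    decomp: ICADecomposition,
    edge_mask: np.ndarray | None = None,
    motion: list[np.ndarray] | None = None,
    edge_fraction_threshold: float = 0.5,
    motion_r_threshold: float = 0.6,
) -> tuple[list[int], pd.DataFrame]:
    """Rule-based artifact screen standing in for visual inspection.

    A component is discarded when the fraction of its absolute map mass
    inside the edge/rim mask exceeds ``edge_fraction_threshold``, or when
    its time course correlates with any motion regressor above
    ``motion_r_threshold`` in any subject.  Returns (retained indices, report).
    """
    if edge_mask is None:
        edge_mask = rim_mask(decomp.grid_shape)
    edge_in_mask = edge_mask[decomp.mask]
    rows = []
    retained = []
    for k in range(decomp.n_components):
        amap = np.abs(decomp.group_maps[k])
        edge_frac = float(amap[edge_in_mask].sum() / max(amap.sum(), 1e-12))
        max_motion_r = 0.0
        if motion is not None:
            for tc, m in zip(decomp.subject_timecourses, motion):
                for j in range(m.shape[1]):
                    mj = m[:, j]
                    if np.std(mj) < 1e-12:
                        continue
                    r = abs(np.corrcoef(tc[k], mj)[0, 1])
                    max_motion_r = max(max_motion_r, float(r))
        keep = edge_frac <= edge_fraction_threshold and max_motion_r <= motion_r_threshold
        rows.append({"component": k, "edge_fraction": edge_frac,
                     "max_motion_r": max_motion_r, "retained": keep})
        if keep:
            retained.append(k)
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# engagement betas


def engagement_betas(
    decomp: ICADecomposition,
    block_timing: pd.DataFrame,
    motion: list[np.ndarray] | None = None,
    tr_s: float = 1.5,
    outlier_sd: float = 2.0,
) -> NetworkEngagement:
    """Per-subject, per-component condition betas and baseline contrasts.

    Design: HRF-convolved boxcars for rest, PL, AS, speech-motor, and the
    test phase (nuisance), six motion regressors, and an intercept; ordinary
    least squares per component time course.  Contrasts: PL - rest and
    AS - mean(rest, speech-motor).  A beta is flagged excluded when it lies
    more than ``outlier_sd`` SDs from the across-subject mean of its
    component x contrast cell.
    """
    n_trs = decomp.subject_timecourses[0].shape[1]
    regs = condition_regressors(block_timing, n_trs, tr_s, CONDITIONS)
    cond_mat = regs.to_numpy()  # (time, 5)
    n_subj = len(decomp.subject_timecourses)
    contrasts = {
        "PL-rest": {"PL": 1.0, "rest": -1.0},
        "AS-baseline": {"AS": 1.0, "rest": -0.5, "speech_motor": -0.5},
    }
    cond_betas = np.zeros((n_subj, decomp.n_components, len(CONDITIONS)))
    betas = np.zeros((n_subj, decomp.n_components, len(contrasts)))
    for s in range(n_subj):
        cols = [cond_mat]
        if motion is not None:
            cols.append(motion[s])
        cols.append(np.ones((n_trs, 1)))
        X = np.hstack(cols)
        zero_cols = np.where(np.ptp(X, axis=0) == 0)[0]
        zero_cols = zero_cols[zero_cols != X.shape[1] - 1]
        if len(zero_cols):
            raise ValueError(f"singular design: constant columns {zero_cols.tolist()}")
        coefs, *_ = np.linalg.lstsq(X, decomp.subject_timecourses[s].T, rcond=None)
        cond_betas[s] = coefs[: len(CONDITIONS)].T
        for ci, weights in enumerate(contrasts.values()):
            vec = np.array([weights.get(c, 0.0) for c in CONDITIONS])
            betas[s, :, ci] = cond_betas[s] @ vec
    mean = betas.mean(axis=0, keepdims=True)
    if n_subj > 1:
        sd = betas.std(axis=0, ddof=1, keepdims=True)
    else:
        sd = np.zeros_like(mean)
    excluded = np.abs(betas - mean) > outlier_sd * np.where(sd > 0, sd, np.inf)
    return NetworkEngagement(
        betas=betas,
        contrast_names=tuple(contrasts),
        excluded=excluded,
        condition_betas=cond_betas,
    )


# ---------------------------------------------------------------------------
# group statistics on betas


def group_network_stats(
    engagement: NetworkEngagement,
    group_labels: list[str],
    components: list[int] | None = None,
) -> pd.DataFrame:
    """Between-group and within-group tests per component x contrast.

    Mann-Whitney between high and low synchronizers, Wilcoxon signed-rank
    against zero within each group; BH-FDR across components separately for
    each test family.  Outlier-flagged betas are excluded observation-wise.
    """
    labels = np.asarray(group_labels)
    comps = components if components is not None else list(range(engagement.betas.shape[1]))
    rows = []
    for ci, cname in enumerate(engagement.contrast_names):
        for k in comps:
            b = engagement.betas[:, k, ci]
            ok = ~engagement.excluded[:, k, ci]
            hi = b[ok & (labels == "high")]
            lo = b[ok & (labels == "low")]
            if len(hi) < 4 or len(lo) < 4:
                raise ValueError("need at least 4 subjects per group after exclusions")
            rows.append({
                "component": k, "contrast": cname,
                "n_high": len(hi), "n_low": len(lo),
                "mean_high": float(hi.mean()), "mean_low": float(lo.mean()),
                "p_between": mann_whitney(hi, lo),
                "p_high_vs0": wilcoxon_signed(hi, 0.0),
                "p_low_vs0": wilcoxon_signed(lo, 0.0),
            })
    df = pd.DataFrame(rows)
    for col in ("p_between", "p_high_vs0", "p_low_vs0"):
        adj = np.empty(len(df))
        for cname in engagement.contrast_names:
            sel = df["contrast"] == cname
            adj[sel.to_numpy()] = bh_fdr(df.loc[sel, col].to_numpy())
        df[col + "_fdr"] = adj
    return df


# ---------------------------------------------------------------------------
# thresholded group maps


def group_map(
    subject_maps: list[np.ndarray],
    component: int,
    mask: np.ndarray,
    voxel_p: float = 0.001,
    extent: int = 50,
    n_permutations: int = 0,
    seed: int = 0,
) -> GroupMap:
    """One-sample t map of a component across subjects, thresholded.

    Voxels with one-sided p < ``voxel_p`` (activation direction) are labeled
    into 26-connected clusters; clusters smaller than ``extent`` voxels are
    removed.  With ``n_permutations`` > 0 a sign-flip permutation null of the
    maximum cluster size additionally prunes clusters at family-wise p >= .05.
    """
    if extent < 1:
        raise ValueError("extent threshold must be at least 1 voxel")
    if len(subject_maps) < 3:
        raise ValueError("group map needs at least 3 subjects")
    stack = np.asarray([m[component] for m in subject_maps])  # (subjects, voxels)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    t_crit = stats.t.isf(voxel_p, df=n - 1)

    structure = np.ones((3, 3, 3), bool)  # 26-connectivity

    def clusters_from(tvals: np.ndarray) -> tuple[np.ndarray, list[dict]]:
        vol = np.zeros(mask.shape)
        vol[mask] = tvals
        supra = (vol > t_crit) & mask
        lab, nlab = ndimage.label(supra, structure=structure)
        out = []
        keep = np.zeros(mask.shape, bool)
        for i in range(1, nlab + 1):
            size = int(np.sum(lab == i))
            if size >= extent:
                keep |= lab == i
                com = ndimage.center_of_mass(lab == i)
                out.append({"label": i, "size": size, "center": tuple(float(c) for c in com)})
        return keep, out

    keep, clusters = clusters_from(t)

    if n_permutations > 0 and clusters:
        rng = np.random.default_rng(seed)
        max_null = []
        for _ in range(n_permutations):
            flips = rng.choice([-1.0, 1.0], size=n)[:, None]
            ps = stack * flips
            pm, psd = ps.mean(axis=0), ps.std(axis=0, ddof=1)
            pt = np.where(psd > 0, pm / (psd / np.sqrt(n)), 0.0)
            _, cl = clusters_from(pt)
            max_null.append(max((c["size"] for c in cl), default=0))
        max_null = np.asarray(max_null)
        surv = []
        keep = np.zeros(mask.shape, bool)
        vol = np.zeros(mask.shape)
        vol[mask] = t
        supra = (vol > t_crit) & mask
        lab, nlab = ndimage.label(supra, structure=structure)
        for c in clusters:
            fwe_p = float((np.sum(max_null >= c["size"]) + 1) / (n_permutations + 1))
            if fwe_p < 0.05:
                c = dict(c, fwe_p=fwe_p)
                surv.append(c)
                keep |= lab == c["label"]
        clusters = surv

    t_vol = np.zeros(mask.shape)
    t_vol[mask] = t
    return GroupMap(t_map=t_vol, thresholded_mask=keep, clusters=clusters,
                    voxel_p=voxel_p, extent=extent)
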