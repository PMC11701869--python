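"""Signed weighted co-expression networks and module detection.

Pipeline: signed adjacency a_ij = ((1 + cor_ij)/2)^beta on VST expression,
topological overlap similarity, average-linkage clustering of 1 - TOM,
dynamic hybrid tree cut (minimum module size plus core-scatter/gap
criteria, followed by a PAM-like assignment of leftover genes), module
eigengenes (first principal component, sign-oriented), merging of modules
whose eigengenes correlate above a threshold, and module-trait Pearson
correlations.

Modules are named by the conventional colour sequence in decreasing size
order, with grey reserved for unassigned genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

#: conventional module colour order (size rank); grey = unassigned
COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
GREY = "grey"


def signed_adjacency(vst_expr: pd.DataFrame, beta: int = 5) -> pd.DataFrame:
    """Signed soft-thresholded adjacency from gene x sample expression."""
    if vst_expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for a co-expression network")
    values = vst_expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    zero_var = np.flatnonzero(sd == 0)
    if len(zero_var):
        raise ValueError(
            f"zero-variance gene {vst_expr.index[zero_var[0]]!r}; remove before networking"
        )
    cor = np.corrcoef(values)
    a = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(a, index=vst_expr.index, columns=vst_expr.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; the diagonal is 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    shared = a @ a
    # remove u = i and u = j terms (diagonal of a is 1)
    inner = shared - a * np.diag(a)[:, None] - a * np.diag(a)[None, :]
    kmin = np.minimum(k[:, None], k[None, :])
    denom = kmin + 1.0 - a
    np.fill_diagonal(denom, 1.0)  # diagonal is overwritten below
    tom = (inner + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def _hybrid_constants(deep_split: int) -> tuple[float, float]:
    """Normalized core-scatter ceiling and minimum gap for a split level."""
    max_core_scatter = 0.64 + 0.075 * deep_split
    min_gap = (1.0 - max_core_scatter) * 0.75
    return max_core_scatter, min_gap


def cut_modules(
    dissimilarity: pd.DataFrame,
    min_module_size: int = 30,
    deep_split: int = 1,
    scatter_attach_ratio: float = 0.85,
) -> pd.Series:
    """Dynamic hybrid module detection on a TOM dissimilarity.

    Stage 1 walks the average-linkage merge sequence bottom-up.  Growing
    branches absorb small straggler clusters; when a branch that is large
    enough (>= ``min_module_size``), internally tight (normalized mean
    scatter below a deep-split-dependent ceiling) and clearly separated
    (joined at a height at least a minimum gap above its own scatter)
    meets another substantial cluster, both sides are closed and assessed:
    a closed branch becomes a module if, after trimming members far from
    its core, it still meets the size, scatter, gap and
    scatter-to-attachment-ratio criteria (the ratio rejects diffuse
    branches of featureless data).

    Stage 2 assigns each leftover gene to the nearest accepted module when
    its mean dissimilarity to the module is below the module's radius (the
    largest member-to-module mean dissimilarity); everything else is grey.
    Returns a gene -> colour label series.
    """
    genes = dissimilarity.index
    n = len(genes)
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes grey", stacklevel=2)
        return pd.Series(GREY, index=genes, name="module")
    d = dissimilarity.to_numpy(dtype=float)
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    heights = Z[:, 2]
    hmin = float(np.percentile(heights, 5))
    hmax = float(heights.max())
    span = max(hmax - hmin, 1e-12)
    max_scatter, min_gap = _hybrid_constants(deep_split)

    accepted: list[np.ndarray] = []

    def scatter_from(pair_total: float, size: int) -> float:
        return pair_total / (size * (size - 1) / 2.0) if size > 1 else 0.0

    def finalize(members: np.ndarray, pair_sum: float, attach: float) -> None:
        """Close a branch: trim to its core, then apply module criteria."""
        if len(members) < min_module_size:
            return
        trimmed, n_tight = _trim_to_core(d, members, min_module_size, attach)
        if len(trimmed) < min_module_size or n_tight < min_module_size:
            return
        cutoff = scatter_attach_ratio * attach
        sub = d[np.ix_(trimmed, trimmed)]
        scatter = float(sub.sum() / (len(trimmed) * (len(trimmed) - 1)))
        scatter_norm = (scatter - hmin) / span
        attach_norm = (attach - hmin) / span
        if (
            scatter_norm <= max_scatter
            and (attach_norm - scatter_norm) >= min_gap
            and scatter <= cutoff
        ):
            accepted.append(trimmed)

    # per active cluster: member indices, sum of pairwise dissimilarities
    # (each unordered pair counted once), composite flag
    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    pair_sum: dict[int, float] = {i: 0.0 for i in range(n)}
    composite: dict[int, bool] = {i: False for i in range(n)}

    def is_separated(mem: np.ndarray, psum: float, h: float) -> bool:
        if len(mem) < min_module_size:
            return False
        sc = scatter_from(psum, len(mem))
        return (h - sc) / span >= min_gap and (sc - hmin) / span <= max_scatter

    for row, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + row
        ma, mb = members.pop(a), members.pop(b)
        sa, sb = pair_sum.pop(a), pair_sum.pop(b)
        ca, cb = composite.pop(a), composite.pop(b)
        cross = float(d[np.ix_(ma, mb)].sum())
        if ca or cb:
            # one side is already closed: close the other side too
            if not ca:
                finalize(ma, sa, h)
            if not cb:
                finalize(mb, sb, h)
            composite[node] = True
        else:
            sep_a = is_separated(ma, sa, h)
            sep_b = is_separated(mb, sb, h)
            big_a = len(ma) >= min_module_size
            big_b = len(mb) >= min_module_size
            if (sep_a and big_b) or (sep_b and big_a):
                finalize(ma, sa, h)
                finalize(mb, sb, h)
                composite[node] = True
            else:
                composite[node] = False
        members[node] = np.concatenate([ma, mb])
        pair_sum[node] = sa + sb + cross

    # the root may still be an open branch
    root = n + len(Z) - 1
    if not composite[root]:
        finalize(members[root], pair_sum[root], hmax)

    labels = np.full(n, -1, dtype=int)
    for mi, mem in enumerate(accepted):
        labels[mem] = mi

    if accepted:
        # PAM-like stage 2 on unassigned genes
        radii = []
        for mem in accepted:
            sub = d[np.ix_(mem, mem)]
            member_avg = sub.sum(axis=1) / (len(mem) - 1)
            radii.append(member_avg.max())
        for g in np.flatnonzero(labels == -1):
            best, best_d = -1, np.inf
            for mi, mem in enumerate(accepted):
                avg = d[g, mem].mean()
                if avg < best_d:
                    best, best_d = mi, avg
            if best >= 0 and best_d < radii[best]:
                labels[g] = best

    return _name_by_size(labels, genes)


def _trim_to_core(
    d: np.ndarray, members: np.ndarray, core_size: int, attach: float,
    trim_fraction: float = 0.5, tight_fraction: float = 0.25,
) -> tuple[np.ndarray, int]:
    """Drop branch members far from the branch core.

    The core is the ``core_size`` members with the lowest mean within-branch
    dissimilarity; a member is kept when its mean dissimilarity to the core
    stays below core scatter + ``trim_fraction`` x (attach - core scatter).
    Background genes chained onto a branch sit near the attachment height
    and are shed here, while genuine members sit near the core scatter.

    Also returns the number of members inside the tighter
    ``tight_fraction`` cutoff: a genuine module must reach the minimum
    size on core-proximal members alone, not by padding with background.
    """
    sub = d[np.ix_(members, members)]
    avg = sub.sum(axis=1) / (len(members) - 1)
    core_local = np.argsort(avg, kind="mergesort")[: min(core_size, len(members))]
    core = members[core_local]
    k = len(core)
    core_d = d[np.ix_(core, core)]
    core_scatter = core_d.sum() / (k * (k - 1)) if k > 1 else 0.0
    headroom = max(attach - core_scatter, 0.0)
    to_core = d[np.ix_(members, core)].mean(axis=1)
    n_tight = int((to_core < core_scatter + tight_fraction * headroom).sum())
    return members[to_core < core_scatter + trim_fraction * headroom], n_tight


def _name_by_size(labels: np.ndarray, genes: pd.Index) -> pd.Series:
    sizes = {}
    for lab in set(labels) - {-1}:
        sizes[lab] = (labels == lab).sum()
    ranked = sorted(sizes, key=lambda lab: (-sizes[lab], lab))
    color_of = {lab: COLOR_SEQUENCE[i] if i < len(COLOR_SEQUENCE) else f"module{i + 1}"
                for i, lab in enumerate(ranked)}
    named = [color_of.get(lab, GREY) if lab != -1 else GREY for lab in labels]
    return pd.Series(named, index=genes, name="module")


def module_eigengenes(vst_expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module (modules x samples).

    Member expression is standardized per gene; the eigengene is scaled to
    unit variance and sign-oriented so its mean correlation with member
    genes is positive.
    """
    modules = sorted(set(labels) - {GREY})
    out = {}
    for mod in modules:
        members = labels.index[labels == mod]
        x = vst_expr.loc[members].to_numpy(dtype=float)
        if len(members) == 1:
            warnings.warn(f"module {mod} has a single gene", stacklevel=2)
        sd = x.std(axis=1, keepdims=True)
        z = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
        u, s, vt = np.linalg.svd(z.T, full_matrices=False)
        eig = u[:, 0]
        eig = eig / eig.std() if eig.std() > 0 else eig
        with np.errstate(divide="ignore", invalid="ignore"):
            cors = np.array([np.corrcoef(eig, row)[0, 1] for row in z])
        mean_cor = float(np.nanmean(cors)) if np.isfinite(cors).any() else 0.0
        if mean_cor < 0 or (mean_cor == 0 and eig[0] < 0):
            eig = -eig
        out[mod] = eig
    eg = pd.DataFrame(out, index=vst_expr.columns).T
    eg.index.name = "module"
    return eg


def merge_close_modules(
    vst_expr: pd.DataFrame, labels: pd.Series, cut_height: float = 0.15
) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity < cut.

    After each merge the eigengenes are recomputed; merging stops when no
    pair of eigengenes has 1 - cor below ``cut_height``.  Merged modules
    are renamed by size afterwards.
    """
    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {GREY})
        if len(modules) < 2:
            break
        eg = module_eigengenes(vst_expr, labels)
        cor = np.corrcoef(eg.to_numpy())
        best_pair, best_diss = None, np.inf
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                diss = 1.0 - cor[i, j]
                if diss < best_diss - 1e-15:
                    best_pair, best_diss = (modules[i], modules[j]), diss
        if best_pair is None or best_diss >= cut_height:
            break
        a, b = best_pair
        labels[labels == b] = a
    # re-rank colours by final sizes
    codes = pd.factorize(labels.where(labels != GREY, None))[0]
    return _name_by_size(codes, labels.index)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of each module eigengene with each trait.

    Missing trait values are pairwise-deleted; p-values come from the
    t-distribution with n_complete - 2 df.  Rows and columns are ordered
    by average-linkage clustering on correlation distance.
    """
    samples = eigengenes.columns.intersection(traits.index)
    eg = eigengenes[samples]
    tr = traits.loc[samples]
    r = pd.DataFrame(np.nan, index=eg.index, columns=tr.columns, dtype=float)
    p = r.copy()
    for mod in eg.index:
        x = eg.loc[mod].to_numpy(dtype=float)
        for trait in tr.columns:
            y = tr[trait].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < 3:
                warnings.warn(
                    f"trait {trait!r} has fewer than 3 complete pairs", stacklevel=2
                )
                continue
            if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            rv = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rv = min(max(rv, -1.0), 1.0)
            if abs(rv) >= 1.0:
                pv = 0.0
            else:
                t = rv * np.sqrt(n - 2) / np.sqrt(1.0 - rv**2)
                pv = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            r.loc[mod, trait] = rv
            p.loc[mod, trait] = pv
    r = _cluster_order(r)
    p = p.loc[r.index, r.columns]
    return r, p


def _cluster_order(r: pd.DataFrame) -> pd.DataFrame:
    """Order rows/columns by average-linkage clustering of correlations."""
    def order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 3:
            return np.arange(mat.shape[0])
        filled = np.nan_to_num(mat)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cor = np.corrcoef(filled)
        cor = np.nan_to_num(cor, nan=0.0)
        dist = squareform(1.0 - cor, checks=False)
        Z = hierarchy.linkage(dist, method="average")
        return hierarchy.leaves_list(Z)

    row_order = order(r.to_numpy())
    col_order = order(r.to_numpy().T)
    return r.iloc[row_order, col_order]


def module_sizes(labels: pd.Series) -> pd.Series:
    """Gene counts per module, decreasing, grey excluded."""
    counts = labels[labels != GREY].value_counts()
    return counts.sort_values(ascending=False)
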