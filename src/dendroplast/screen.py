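"""Differential expression and the CNO-amelioration screen.

The expression stage mirrors a standard limma-style bulk RNA-seq workflow
on the four-group design (EtOH/H2O x CNO/VEH):

1. library-size normalization to log2 counts per million,
   ``log2((count + 0.5) / (libsize + 1) * 1e6)``, with genes below a mean
   abundance of 1 CPM dropped;
2. a gene-wise cell-means linear model over the four groups with
   empirical-Bayes moderated t-statistics — gene residual variances
   ``s_g^2`` (on ``d_g`` df) are shrunk toward a prior ``s_0^2`` (on ``d_0``
   df) estimated by moment matching of ``log s_g^2`` against a scaled-F
   distribution, and contrasts are tested on ``d_0 + d_g`` df;
3. DEG calls at unadjusted p < 0.05 per contrast against the H2O(VEH)
   control, a three-set partition of the DEG lists (the Venn regions), and
   a per-gene Euclidean-distance ranking that scores how strongly a
   binge-responsive expression change is absent under CNO ("amelioration");
4. a report of a curated panel of structural-plasticity mediator genes
   under the two within-treatment EtOH vs H2O contrasts.

Precision weights (voom) are deliberately not applied; the moderated t is
computed on unweighted log-CPM.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

CONTROL_GROUP = "H2O_VEH"
NONCONTROL_GROUPS = ("EtOH_VEH", "EtOH_CNO", "H2O_CNO")


# ---------------------------------------------------------------------------
# log-CPM
# ---------------------------------------------------------------------------

def logcpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None,
           min_mean_cpm: float | None = 1.0) -> pd.DataFrame:
    """log2 counts per million with a 0.5 pseudo-count.

    ``lib_sizes`` defaults to column sums.  Genes whose mean plain CPM falls
    below ``min_mean_cpm`` are dropped (pass ``None`` to keep everything);
    the number removed is logged.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib = lib_sizes.to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be > 0")
    out = counts
    if min_mean_cpm is not None:
        cpm = counts.to_numpy() / lib * 1e6
        keep = cpm.mean(axis=1) >= min_mean_cpm
        dropped = int((~keep).sum())
        if dropped:
            logger.info("logcpm: dropped %d/%d genes below %.3g mean CPM",
                        dropped, counts.shape[0], min_mean_cpm)
        out = counts.loc[keep]
    vals = np.log2((out.to_numpy() + 0.5) / (lib + 1.0) * 1e6)
    return pd.DataFrame(vals, index=out.index, columns=out.columns)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, max_iter: int = 50, tol: float = 1e-8
                      ) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """(d0, s0^2) by moment matching of log s_g^2 (Smyth-style).

    Returns ``d0 = inf`` when the observed spread of log variances is no
    larger than the sampling spread of a chi-square on ``df`` degrees of
    freedom (i.e. the gene variances look exchangeable).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive gene variances to fit the prior")
    e = np.log(s2[ok]) - digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    emean = float(np.mean(e))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


class ModeratedTDE(BaseEstimator):
    """Gene-wise cell-means model with empirical-Bayes variance shrinkage.

    scikit-learn style: ``fit(X, y)`` with ``X`` of shape
    (n_samples, n_genes) and ``y`` the group label per sample; ``contrast``
    then tests any pair of groups per gene.

    Parameters
    ----------
    prior_df : None to estimate d0 empirically; 0 recovers the ordinary
        t-test; ``numpy.inf`` pools every gene's variance at s0^2.
    fallback_prior_df : used, with a warning, when d0 estimation fails.
    alpha : DEG threshold on the (unadjusted) two-sided p-value.

    Fitted attributes: ``means_`` (n_groups x n_genes), ``s2_``,
    ``df_residual_``, ``prior_df_``, ``prior_var_``, ``var_post_``.
    """

    def __init__(self, prior_df: float | None = None,
                 fallback_prior_df: float = 10.0, alpha: float = 0.05):
        self.prior_df = prior_df
        self.fallback_prior_df = fallback_prior_df
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_genes) matching y")
        groups, codes = np.unique(y, return_inverse=True)
        k = len(groups)
        n = X.shape[0]
        if n - k < 1:
            raise ValueError("no residual degrees of freedom")
        counts = np.bincount(codes).astype(float)
        if np.any(counts < 2):
            raise ValueError("every group needs >= 2 samples")
        means = np.zeros((k, X.shape[1]))
        for g in range(k):
            means[g] = X[codes == g].mean(axis=0)
        resid = X - means[codes]
        df = float(n - k)
        s2 = (resid ** 2).sum(axis=0) / df

        if self.prior_df is None:
            try:
                d0, s02 = estimate_prior(s2, df)
            except ValueError as exc:
                warnings.warn(
                    f"prior df estimation failed ({exc}); falling back to "
                    f"d0 = {self.fallback_prior_df}", stacklevel=2)
                d0 = float(self.fallback_prior_df)
                s02 = float(np.median(s2)) if np.isfinite(
                    np.median(s2)) else 1.0
        else:
            d0 = float(self.prior_df)
            s02 = float(np.median(s2[np.isfinite(s2) & (s2 > 0)])) \
                if d0 > 0 else 0.0
            if d0 > 0 and not np.isfinite(s02):
                s02 = 1.0
        if np.isinf(d0):
            var_post = np.full_like(s2, s02)
        elif d0 == 0:
            var_post = s2.copy()
        else:
            var_post = (d0 * s02 + df * s2) / (d0 + df)

        self.groups_ = [str(g) for g in groups]
        self.group_sizes_ = {str(g): int(c) for g, c in zip(groups, counts)}
        self.means_ = means
        self.s2_ = s2
        self.df_residual_ = df
        self.prior_df_ = d0
        self.prior_var_ = s02
        self.var_post_ = var_post
        self.genes_ = getattr(X, "columns", None)
        return self

    def contrast(self, a: str, b: str,
                 genes=None) -> pd.DataFrame:
        """Moderated t-test of group ``a`` minus group ``b``, per gene."""
        for g in (a, b):
            if g not in self.groups_:
                raise KeyError(f"group {g!r} not present in the fitted data")
        ia, ib = self.groups_.index(a), self.groups_.index(b)
        na, nb = self.group_sizes_[a], self.group_sizes_[b]
        lfc = self.means_[ia] - self.means_[ib]
        se = np.sqrt(self.var_post_ * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, lfc / se, 0.0)
        df_total = self.prior_df_ + self.df_residual_
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        out = pd.DataFrame({
            "lfc": lfc, "t": t, "p": p, "deg": p < self.alpha})
        if genes is not None:
            out.index = pd.Index(genes, name="gene")
        out.attrs["contrast"] = (a, b)
        out.attrs["prior_df"] = self.prior_df_
        out.attrs["prior_var"] = self.prior_var_
        return out


def moderated_t_de(log_expr: pd.DataFrame, metadata: pd.DataFrame,
                   contrast: tuple[str, str],
                   prior_df: float | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Convenience wrapper: genes x samples log-expression in, DETable out."""
    meta = metadata.set_index("sample").loc[log_expr.columns]
    model = ModeratedTDE(prior_df=prior_df, alpha=alpha)
    model.fit(log_expr.to_numpy().T, meta["group"].to_numpy())
    return model.contrast(*contrast, genes=log_expr.index)


def de_vs_control(log_expr: pd.DataFrame, metadata: pd.DataFrame,
                  prior_df: float | None = None, alpha: float = 0.05
                  ) -> dict[str, pd.DataFrame]:
    """The three DEG tables against the H2O(VEH) control (one shared fit)."""
    meta = metadata.set_index("sample").loc[log_expr.columns]
    model = ModeratedTDE(prior_df=prior_df, alpha=alpha)
    model.fit(log_expr.to_numpy().T, meta["group"].to_numpy())
    return {g: model.contrast(g, CONTROL_GROUP, genes=log_expr.index)
            for g in NONCONTROL_GROUPS}


# ---------------------------------------------------------------------------
# set partition, amelioration ranking, panel report
# ---------------------------------------------------------------------------

def venn_partition(sets: dict[str, set]) -> pd.DataFrame:
    """Disjoint regions of a three-set overlap, with counts and members.

    Returns one row per region (7 rows), with a ``region`` label naming the
    sets the genes belong to (e.g. ``"EtOH_VEH_only"``,
    ``"EtOH_VEH&EtOH_CNO"``, ``"all"``), a count, and the sorted member
    list.  Region counts sum to the size of the union.
    """
    if len(sets) != 3:
        raise ValueError("venn_partition expects exactly three named sets")
    names = list(sets)
    a, b, c = (set(sets[n]) for n in names)
    regions = {
        f"{names[0]}_only": a - b - c,
        f"{names[1]}_only": b - a - c,
        f"{names[2]}_only": c - a - b,
        f"{names[0]}&{names[1]}": (a & b) - c,
        f"{names[0]}&{names[2]}": (a & c) - b,
        f"{names[1]}&{names[2]}": (b & c) - a,
        "all": a & b & c,
    }
    return pd.DataFrame({
        "region": list(regions),
        "count": [len(v) for v in regions.values()],
        "genes": [sorted(v) for v in regions.values()],
    })


def amelioration_distance(lfc: pd.DataFrame,
                          mode: str = "etoh_pair") -> pd.Series:
    """Per-gene Euclidean distance between contrast effect patterns.

    ``lfc`` must have one column per non-control contrast
    (EtOH_VEH, EtOH_CNO, H2O_CNO).  ``mode='etoh_pair'`` (default) measures
    the distance between the EtOH(VEH) and EtOH(CNO) effects — large when
    the binge response is absent under CNO; ``mode='all_pairs'`` uses the
    full pairwise distance among all three contrast effects.
    """
    cols = list(NONCONTROL_GROUPS)
    missing = [cnm for cnm in cols if cnm not in lfc.columns]
    if missing:
        raise KeyError(f"missing contrast columns: {missing}")
    if mode == "etoh_pair":
        d = np.abs(lfc["EtOH_VEH"] - lfc["EtOH_CNO"])
    elif mode == "all_pairs":
        sq = sum((lfc[x] - lfc[y]) ** 2 for x, y in combinations(cols, 2))
        d = np.sqrt(sq)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(np.asarray(d, dtype=float), index=lfc.index,
                     name="distance")


def amelioration_rank(detables: dict[str, pd.DataFrame],
                      genes=None, mode: str = "etoh_pair") -> pd.DataFrame:
    """Rank genes by how strongly CNO removes their binge response.

    ``detables`` maps each non-control contrast to its DE table (as from
    :func:`de_vs_control`).  ``genes`` restricts the ranking (the screen is
    usually run on the DEGs unique to EtOH(VEH)); by default every gene with
    all three contrasts available is ranked.  Ties are broken by gene id;
    rank 1 is the largest distance.
    """
    lfc = pd.DataFrame({g: detables[g]["lfc"] for g in NONCONTROL_GROUPS})
    if genes is not None:
        genes = [g for g in genes]
        missing = set(genes) - set(lfc.index)
        if missing:
            raise KeyError(f"genes absent from DE tables: {sorted(missing)}")
        lfc = lfc.loc[genes]
    out = lfc.copy()
    out.columns = [f"lfc_{g}" for g in NONCONTROL_GROUPS]
    out["distance"] = amelioration_distance(lfc, mode=mode)
    # descending distance, ascending gene id on ties
    out = out.iloc[np.lexsort((out.index.to_numpy(),
                               -out["distance"].to_numpy()))]
    out["rank"] = np.arange(1, len(out) + 1)
    out.index.name = "gene"
    return out


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def mediator_panel_report(de_veh: pd.DataFrame, de_cno: pd.DataFrame,
                          panel: list[str]) -> pd.DataFrame:
    """Panel-gene expression under the two within-treatment contrasts.

    ``de_veh`` and ``de_cno`` are DE tables for EtOH vs H2O within VEH and
    within CNO.  Returns exactly one row per panel gene, in panel order;
    genes absent from the data are flagged ``missing`` rather than dropped.
    """
    rows = []
    for gene in panel:
        row: dict = {"gene": gene}
        missing = gene not in de_veh.index or gene not in de_cno.index
        row["missing"] = bool(missing)
        for label, tab in (("veh", de_veh), ("cno", de_cno)):
            if missing:
                row[f"lfc_{label}"] = np.nan
                row[f"p_{label}"] = np.nan
                row[f"stars_{label}"] = ""
            else:
                row[f"lfc_{label}"] = float(tab.loc[gene, "lfc"])
                row[f"p_{label}"] = float(tab.loc[gene, "p"])
                row[f"stars_{label}"] = _stars(float(tab.loc[gene, "p"]))
        rows.append(row)
    return pd.DataFrame(rows)
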