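"""Hurdle-model differential expression of (cell type, sample) strata.

The test is the standard two-part construction for zero-inflated
single-cell expression: a discrete (logistic/binomial) component models
detection (value > 0), a continuous (Gaussian) component models the
magnitude of the positive values on the log2 scale, each with and without
a foreground/background indicator.  The two likelihood-ratio statistics
are summed and referred to a chi-square whose degrees of freedom equal the
number of components that could actually be fitted (2 normally; 1 when a
component is degenerate).  No latent covariates are used: the only model
term is the group indicator.

Fold changes are differences of log2(linear mean + pseudocount) between
foreground and background, so that downstream receptor-ligand scores —
log2 of products of linear fold changes — are plain sums of the log2 fold
changes reported here.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

_RSS_EPS = 1e-12


class HurdleResult(NamedTuple):
    stat: float
    df: int
    p: float


def _binomial_lr(k1, n1, k2, n2):
    """LR statistic of detection ~ group vs detection ~ 1 (2x2 G-test)."""
    p1 = k1 / n1
    p2 = k2 / n2
    pp = (k1 + k2) / (n1 + n2)

    def ll(k, n, p):
        return xlogy(k, p) + xlogy(n - k, 1.0 - p)

    return 2.0 * (ll(k1, n1, p1) + ll(k2, n2, p2) - ll(k1, n1, pp) - ll(k2, n2, pp))


def _hurdle_core(k1, n1, k2, n2, m1, s1, ss1, m2, s2, ss2):
    """Vectorized hurdle LRT from sufficient statistics.

    k/n: detected / total cells per group; m/s/ss: count, sum, and sum of
    squares of the positive values per group.  All arguments broadcast as
    float arrays; returns (stat, df, p) arrays.
    """
    k1, k2 = np.asarray(k1, float), np.asarray(k2, float)
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)

    undetected = (k1 + k2) == 0
    fit_disc = ~undetected & ~((k1 == n1) & (k2 == n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        lr_disc = np.where(fit_disc, _binomial_lr(k1, n1, k2, n2), 0.0)

    n_pos = m1 + m2
    with np.errstate(invalid="ignore", divide="ignore"):
        rss0 = np.clip(ss1 + ss2 - (s1 + s2) ** 2 / np.maximum(n_pos, 1), 0.0, None)
        rss1 = np.clip(
            (ss1 - np.where(m1 > 0, s1**2 / np.maximum(m1, 1), 0.0))
            + (ss2 - np.where(m2 > 0, s2**2 / np.maximum(m2, 1), 0.0)),
            0.0,
            None,
        )
    fit_cont = (m1 >= 1) & (m2 >= 1) & (rss1 > _RSS_EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        lr_cont = np.where(
            fit_cont, n_pos * np.log(np.maximum(rss0, _RSS_EPS) / np.maximum(rss1, _RSS_EPS)), 0.0
        )
    lr_cont = np.clip(lr_cont, 0.0, None)

    stat = np.where(fit_disc, lr_disc, 0.0) + lr_cont
    stat = np.clip(stat, 0.0, None)
    df = fit_disc.astype(int) + fit_cont.astype(int)
    p = np.where(df > 0, chi2.sf(stat, np.maximum(df, 1)), 1.0)
    return stat, df, p


def hurdle_test(fg: np.ndarray, bg: np.ndarray) -> HurdleResult:
    """Two-part hurdle likelihood-ratio test of foreground vs background.

    Inputs are vectors of log2-normalized expression values for the two
    groups.  Degenerate situations follow the hurdle contract: a gene
    undetected in both groups gives (0, 0, 1); all values positive in both
    groups drops the discrete component; constant positive values drop the
    continuous component.
    """
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("fg and bg must each be nonempty")
    pos1, pos2 = fg[fg > 0], bg[bg > 0]
    stat, df, p = _hurdle_core(
        (fg > 0).sum(), fg.size, (bg > 0).sum(), bg.size,
        pos1.size, pos1.sum(), (pos1**2).sum(),
        pos2.size, pos2.sum(), (pos2**2).sum(),
    )
    return HurdleResult(float(stat), int(df), float(p))


def detection_fraction(v: np.ndarray) -> float:
    """Fraction of entries strictly greater than zero."""
    v = np.asarray(v)
    if v.size == 0:
        raise ValueError("empty vector")
    return float((v > 0).mean())


def log_fold_change(fg: np.ndarray, bg: np.ndarray, pseudocount: float = 1.0) -> float:
    """log2 fold change of linear means of log2-normalized values.

    log2(mean(2^fg - 1) + pseudocount) - log2(mean(2^bg - 1) + pseudocount).
    """
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("fg and bg must each be nonempty")
    m_fg = float(np.mean(np.exp2(fg) - 1.0))
    m_bg = float(np.mean(np.exp2(bg) - 1.0))
    return float(np.log2(m_fg + pseudocount) - np.log2(m_bg + pseudocount))


def adjust_pvalues(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_by_celltype_sample(
    nm: ad.AnnData,
    gene_set: Sequence[str],
    min_cells: int = 3,
    background: str = "other_types",
    family: str = "pooled",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Hurdle DE of every (cell type, sample) stratum against the pooled rest.

    For each gene in ``gene_set`` and each (cell_type, sample_id) stratum,
    the foreground is the cells of that type in that sample and the
    background is the pooled cells of all other cell types across all
    samples (``background="other_types"``, the default); alternatives are
    the strict complement of the foreground (``"complement"``) or other
    cell types restricted to the stratum's own group (``"within_group"``).
    Strata with fewer than ``min_cells`` cells are emitted flagged with
    p = 1 rather than tested.  BH adjustment is over the whole table
    (``family="pooled"``) or per stratum (``"per_stratum"``).
    """
    if len(gene_set) == 0:
        raise ValueError("gene_set must be nonempty")
    missing = [g for g in gene_set if g not in nm.var_names]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:10]}")
    for col in ("cell_type", "sample_id", "group_id"):
        if col not in nm.obs.columns:
            raise ValueError(f"annotation column {col!r} missing from obs")
    if background not in ("other_types", "complement", "within_group"):
        raise ValueError(f"unknown background mode {background!r}")
    if family not in ("pooled", "per_stratum"):
        raise ValueError(f"unknown family mode {family!r}")

    genes = list(gene_set)
    X = nm[:, genes].X
    V = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    pos = V > 0
    linear = np.exp2(V) - 1.0

    ctype = nm.obs["cell_type"].to_numpy()
    sample = nm.obs["sample_id"].to_numpy()
    group = nm.obs["group_id"].to_numpy()
    strata = (
        pd.DataFrame({"cell_type": ctype, "sample_id": sample, "group_id": group})
        .drop_duplicates()
        .sort_values(["cell_type", "sample_id"])
        .itertuples(index=False)
    )

    frames = []
    for st in strata:
        fg = (ctype == st.cell_type) & (sample == st.sample_id)
        if background == "other_types":
            bg = ctype != st.cell_type
        elif background == "within_group":
            bg = (ctype != st.cell_type) & (group == st.group_id)
        else:
            bg = ~fg
        n1, n2 = int(fg.sum()), int(bg.sum())
        rec = pd.DataFrame({"gene": genes})
        rec["cell_type"] = st.cell_type
        rec["sample_id"] = st.sample_id
        rec["group_id"] = st.group_id

        if n1 == 0 or n2 == 0:
            continue
        lm_fg = linear[fg].mean(axis=0)
        lm_bg = linear[bg].mean(axis=0)
        rec["log2fc"] = np.log2(lm_fg + pseudocount) - np.log2(lm_bg + pseudocount)
        rec["pct_fg"] = pos[fg].mean(axis=0)
        rec["pct_bg"] = pos[bg].mean(axis=0)

        if n1 < min_cells:
            rec["lrt_stat"], rec["df"], rec["p"] = 0.0, 0, 1.0
            rec["status"] = "too_few_cells"
        else:
            Vf, Vb = V[fg], V[bg]
            pf, pb = pos[fg], pos[bg]
            stat, df, p = _hurdle_core(
                pf.sum(axis=0), n1, pb.sum(axis=0), n2,
                pf.sum(axis=0), np.where(pf, Vf, 0.0).sum(axis=0),
                np.where(pf, Vf**2, 0.0).sum(axis=0),
                pb.sum(axis=0), np.where(pb, Vb, 0.0).sum(axis=0),
                np.where(pb, Vb**2, 0.0).sum(axis=0),
            )
            rec["lrt_stat"], rec["df"], rec["p"] = stat, df, p
            rec["status"] = "ok"
        frames.append(rec)

    table = pd.concat(frames, ignore_index=True)
    if family == "pooled":
        table["p_adj"] = adjust_pvalues(table["p"].to_numpy())
    else:
        table["p_adj"] = (
            table.groupby(["cell_type", "sample_id"], observed=True)["p"]
            .transform(lambda s: adjust_pvalues(s.to_numpy()))
        )
    return table
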