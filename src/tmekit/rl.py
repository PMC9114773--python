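"""Receptor-ligand interaction scoring between a sender and a receiver cell type.

An interaction between a ligand expressed by the sender type and a
receptor expressed by the receiver type is scored per sample as

    RL-score = log2(FC_ligand x FC_receptor)
             = ligand_log2fc + receptor_log2fc,

where the fold changes come from the hurdle differential-expression table
(one (cell type, sample) stratum against the pooled background).  An edge
is flagged significant for a condition group only when, in EVERY sample of
that group, both partners are differentially expressed below the adjusted
p-value threshold, the ligand's log2 FC clears its minimum (default 0.5,
inclusive), and the receptor's log2 FC is strictly positive.  Scores are
reported for all edges whether or not they are flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from tmekit.de import de_by_celltype_sample
from tmekit.preprocess import QCThresholds, filter_cells, normalize

log = logging.getLogger(__name__)

GROUP_AGGREGATE = "__group_mean__"

_KNOWN_MODES = {"stimulation", "inhibition"}


@dataclass
class FilterConfig:
    """Significance and effect-size cutoffs for the consistency filter."""

    p_adj_threshold: float = 0.01
    ligand_log2fc_min: float = 0.5  # inclusive
    receptor_log2fc_min: float = 0.0  # exclusive

    def validate(self) -> None:
        if not 0.0 < self.p_adj_threshold < 1.0:
            raise ValueError("p_adj_threshold must be in (0, 1)")
        for name in ("ligand_log2fc_min", "receptor_log2fc_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def load_interaction_prior(path) -> pd.DataFrame:
    """Load a ligand->receptor prior table, keeping only usable edges.

    The file is a TSV with columns ``ligand``, ``receptor``, ``directed``
    (0/1), ``mode``.  Edges lacking directedness or a known mode of action
    (stimulation/inhibition) are dropped with a logged count, and duplicate
    (ligand, receptor) pairs are collapsed to one edge.
    """
    prior = pd.read_csv(path, sep="\t", dtype={"ligand": str, "receptor": str})
    required = {"ligand", "receptor", "directed", "mode"}
    missing = required - set(prior.columns)
    if missing:
        raise ValueError(f"prior file missing columns: {sorted(missing)}")
    n_raw = len(prior)
    mode = prior["mode"].fillna("").astype(str).str.strip().str.lower()
    keep = (prior["directed"].fillna(0).astype(int) == 1) & mode.isin(_KNOWN_MODES)
    prior = prior[keep].copy()
    prior["mode"] = mode[keep]
    n_dropped = n_raw - len(prior)
    if n_dropped:
        log.info("prior: dropped %d/%d edges without direction or known mode", n_dropped, n_raw)
    n_before = len(prior)
    prior = prior.drop_duplicates(subset=["ligand", "receptor"], keep="first")
    if len(prior) < n_before:
        log.info("prior: collapsed %d duplicate edges", n_before - len(prior))
    if prior.empty:
        warnings.warn("interaction prior is empty after filtering", stacklevel=2)
    return prior.reset_index(drop=True)


def score_interactions(
    de: pd.DataFrame,
    prior: pd.DataFrame,
    sender_type: str,
    receiver_type: str,
    group_id: str,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score every prior edge per sample of a group, plus a group mean.

    Ligand statistics come from the (ligand, sender_type, sample) DE
    record, receptor statistics from (receptor, receiver_type, sample);
    ``rl_score = ligand_log2fc + receptor_log2fc``.  One extra record per
    edge carries the group aggregate (arithmetic mean of the per-sample
    scores) with ``sample_id`` set to :data:`GROUP_AGGREGATE`.  Edges whose
    ligand or receptor is absent from the DE table are skipped with a
    logged count.
    """
    if samples is None:
        samples = sorted(de.loc[de["group_id"] == group_id, "sample_id"].unique())
    samples = list(samples)
    if not samples:
        raise ValueError(f"group {group_id!r} has no samples in the DE table")

    lig = de[(de["cell_type"] == sender_type) & (de["sample_id"].isin(samples))]
    rec = de[(de["cell_type"] == receiver_type) & (de["sample_id"].isin(samples))]
    lig = lig.set_index(["gene", "sample_id"])
    rec = rec.set_index(["gene", "sample_id"])

    rows = []
    n_skipped = 0
    for edge in prior.itertuples(index=False):
        have = all((edge.ligand, s) in lig.index for s in samples) and all(
            (edge.receptor, s) in rec.index for s in samples
        )
        if not have:
            n_skipped += 1
            continue
        per_sample_scores = []
        for s in samples:
            lrow = lig.loc[(edge.ligand, s)]
            rrow = rec.loc[(edge.receptor, s)]
            score = float(lrow["log2fc"] + rrow["log2fc"])
            per_sample_scores.append(score)
            rows.append(
                {
                    "ligand": edge.ligand,
                    "receptor": edge.receptor,
                    "sender": sender_type,
                    "receiver": receiver_type,
                    "group_id": group_id,
                    "sample_id": s,
                    "rl_score": score,
                    "ligand_log2fc": float(lrow["log2fc"]),
                    "receptor_log2fc": float(rrow["log2fc"]),
                    "ligand_p_adj": float(lrow["p_adj"]),
                    "receptor_p_adj": float(rrow["p_adj"]),
                    "mode": getattr(edge, "mode", ""),
                }
            )
        rows.append(
            {
                "ligand": edge.ligand,
                "receptor": edge.receptor,
                "sender": sender_type,
                "receiver": receiver_type,
                "group_id": group_id,
                "sample_id": GROUP_AGGREGATE,
                "rl_score": float(np.mean(per_sample_scores)),
                "ligand_log2fc": np.nan,
                "receptor_log2fc": np.nan,
                "ligand_p_adj": np.nan,
                "receptor_p_adj": np.nan,
                "mode": getattr(edge, "mode", ""),
            }
        )
    if n_skipped:
        log.info("rl: skipped %d edges with genes absent from the DE table", n_skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "ligand", "receptor", "sender", "receiver", "group_id", "sample_id",
            "rl_score", "ligand_log2fc", "receptor_log2fc",
            "ligand_p_adj", "receptor_p_adj", "mode",
        ],
    )


def flag_significant(
    records: pd.DataFrame,
    fc: FilterConfig | None = None,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Apply the all-samples-of-the-group consistency filter.

    An edge is significant iff in every sample of the group:
    ``ligand_p_adj < threshold``, ``receptor_p_adj < threshold``,
    ``ligand_log2fc >= ligand_log2fc_min`` and
    ``receptor_log2fc > receptor_log2fc_min``.  All records are retained;
    the flag is set on per-sample and aggregate records alike.  Edges
    missing a sample record cannot be flagged (logged).
    """
    fc = fc or FilterConfig()
    fc.validate()
    out = records.copy()
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        return out
    if samples is None:
        samples = sorted(s for s in out["sample_id"].unique() if s != GROUP_AGGREGATE)
    samples = set(samples)

    per_sample = out[out["sample_id"] != GROUP_AGGREGATE]
    passes = (
        (per_sample["ligand_p_adj"] < fc.p_adj_threshold)
        & (per_sample["receptor_p_adj"] < fc.p_adj_threshold)
        & (per_sample["ligand_log2fc"] >= fc.ligand_log2fc_min)
        & (per_sample["receptor_log2fc"] > fc.receptor_log2fc_min)
    )
    keycols = ["ligand", "receptor", "sender", "receiver", "group_id"]
    summary = per_sample.assign(_pass=passes).groupby(keycols, observed=True).agg(
        all_pass=("_pass", "all"), n_samples=("sample_id", "nunique")
    )
    complete = summary["n_samples"] == len(samples)
    n_incomplete = int((~complete).sum())
    if n_incomplete:
        log.info("rl: %d edges missing sample records; cannot be flagged", n_incomplete)
    sig = (summary["all_pass"] & complete).rename("significant")
    out = out.merge(sig.reset_index(), on=keycols, how="left")
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out


def heatmap_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Edges x samples matrix of RL scores, with a significance column.

    Rows are "ligand->receptor" edges; columns the per-sample scores, the
    group mean, and the significant flag — ready for external plotting.
    """
    if records.empty:
        return pd.DataFrame()
    key = records["ligand"] + "->" + records["receptor"]
    mat = records.assign(edge=key).pivot_table(
        index="edge", columns="sample_id", values="rl_score", observed=True
    )
    flags = records.assign(edge=key).groupby("edge", observed=True)["significant"].any()
    mat["significant"] = flags
    return mat


def run_rl_pipeline(
    counts: ad.AnnData,
    prior: pd.DataFrame | str,
    sender_type: str,
    receiver_types: Sequence[str],
    group_id: str,
    qc: QCThresholds | None = None,
    fc: FilterConfig | None = None,
    min_cells: int = 3,
    background: str = "other_types",
    outdir=None,
) -> dict[str, pd.DataFrame]:
    """QC -> normalize -> DE on the prior's gene universe -> score -> flag.

    Runs the communication analysis end to end for one sender type against
    each receiver type, and returns per-receiver scored tables plus
    heatmap-ready matrices.  When ``outdir`` is given the tables are also
    written as TSV.
    """
    if isinstance(prior, str) or hasattr(prior, "__fspath__"):
        prior = load_interaction_prior(prior)
    fc = fc or FilterConfig()
    if prior.empty:
        warnings.warn("empty interaction prior; nothing to score", stacklevel=2)
        return {}

    filtered = filter_cells(counts, qc)
    if filtered.n_obs == 0:
        warnings.warn("no cells survived QC; nothing to score", stacklevel=2)
        return {}
    nm = normalize(filtered)

    universe = sorted(
        (set(prior["ligand"]) | set(prior["receptor"])) & set(nm.var_names)
    )
    if not universe:
        warnings.warn("no prior genes present in the matrix", stacklevel=2)
        return {}
    de = de_by_celltype_sample(nm, universe, min_cells=min_cells, background=background)

    samples = sorted(nm.obs.loc[nm.obs["group_id"] == group_id, "sample_id"].unique())
    if not samples:
        raise ValueError(f"group {group_id!r} has no cells after QC")

    results: dict[str, pd.DataFrame] = {"de_table": de}
    for receiver in receiver_types:
        scored = score_interactions(de, prior, sender_type, receiver, group_id, samples)
        flagged = flag_significant(scored, fc, samples)
        results[receiver] = flagged
        results[f"{receiver}_heatmap"] = heatmap_matrix(flagged)
        if outdir is not None:
            import pathlib

            outdir = pathlib.Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            flagged.to_csv(outdir / f"rl_{sender_type}_to_{receiver}.tsv", sep="\t", index=False)
            results[f"{receiver}_heatmap"].to_csv(
                outdir / f"rl_{sender_type}_to_{receiver}_matrix.tsv", sep="\t"
            )
    return results
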