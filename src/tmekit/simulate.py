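"""Synthetic data generators with planted ground truth.

Three generators cover the three kinds of input the pipeline consumes:

* :func:`simulate_counts` — a gene x cell negative-binomial count matrix
  with per-cell library-size variation, logistic dropout, multiple cell
  types, and multiple biological-replicate samples per condition group,
  with fold changes planted on designated (gene, cell type, sample) strata;
* :func:`simulate_interaction_prior` — an OmniPath-style directed
  ligand->receptor edge list containing the planted true interactions plus
  decoys and (optionally) edges with missing mode of action, to exercise
  the prior-subsetting filter;
* :func:`simulate_mxif_image` — a multichannel immunofluorescence image
  with geometric regions painted into marker channels over Gaussian noise,
  with the exact pixel sets recorded as ground truth.

All generators are deterministic given their config's seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import expit


class SimConfigError(ValueError):
    """Raised when a simulation config is invalid; message names the field."""


# ---------------------------------------------------------------------------
# scRNA-seq counts
# ---------------------------------------------------------------------------

DEFAULT_CELL_TYPES = ("CAF1", "CAF2", "Tumor", "Squamous", "Other")

#: Condition groups default to the replicate design of the study the
#: generator emulates: 3 samples for the inflammation-driven tumor model,
#: 2 for the sporadic adenoma model.
DEFAULT_GROUPS: Mapping[str, tuple[str, ...]] = {
    "AOMDSS": ("AD1", "AD2", "AD3"),
    "APC": ("APC1", "APC2"),
}


@dataclass
class SimConfig:
    """Parameters of the negative-binomial scRNA-seq count generator.

    Counts for gene g in cell c are drawn NB with mean
    ``gene_mean[g] * cell_scale[c] * 2**planted_log2fc[g, c]`` and size
    (dispersion) parameter ``dispersion``; per-gene baseline means are
    log-normal around ``baseline_mean``, per-cell scale factors log-normal
    with log-sd ``library_size_spread`` (mean 1).  Dropout then zeroes each
    entry with probability logistic in the log2 NB mean (midpoint
    ``dropout_midpoint``, slope ``dropout_slope``), adding the technical
    zeros the downstream hurdle test exists to handle.
    """

    n_genes: int = 100
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES
    groups: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_GROUPS.items()}
    )
    cells_per_type_per_sample: int = 200
    baseline_mean: float = 2.0
    gene_mean_log_sd: float = 0.6
    dispersion: float = 2.0
    library_size_spread: float = 0.35
    dropout_midpoint: float = -6.0
    dropout_slope: float = 0.4
    #: (gene, cell_type, sample_id or "all", log2 fold change)
    planted_effects: Sequence[tuple[str, str, str, float]] = ()
    mito_gene_count: int = 5
    seed: int = 0

    def gene_names(self) -> list[str]:
        n_reg = self.n_genes - self.mito_gene_count
        names = [f"g{i:04d}" for i in range(n_reg)]
        # mitochondrial genes follow mouse nomenclature so the QC filter can
        # find them by the "mt-" prefix
        names += [f"mt-{i}" for i in range(self.mito_gene_count)]
        return names

    def sample_ids(self) -> list[str]:
        return [s for samples in self.groups.values() for s in samples]

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise SimConfigError("n_genes must be positive")
        if self.mito_gene_count < 0 or self.mito_gene_count > self.n_genes:
            raise SimConfigError("mito_gene_count must be in [0, n_genes]")
        if self.cells_per_type_per_sample <= 0:
            raise SimConfigError("cells_per_type_per_sample must be positive")
        for name in ("baseline_mean", "dispersion", "library_size_spread"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be strictly positive")
        if self.gene_mean_log_sd < 0:
            raise SimConfigError("gene_mean_log_sd must be nonnegative")
        if not self.cell_types:
            raise SimConfigError("cell_types must be nonempty")
        if not self.groups:
            raise SimConfigError("groups must be nonempty")
        for gid, samples in self.groups.items():
            if len(samples) < 1:
                raise SimConfigError(f"groups[{gid!r}] must contain >= 1 sample")
        all_samples = self.sample_ids()
        if len(set(all_samples)) != len(all_samples):
            raise SimConfigError("groups: sample_ids must be unique across groups")
        genes = set(self.gene_names())
        samples = set(all_samples)
        for gene, ctype, sample, _lfc in self.planted_effects:
            if gene not in genes:
                raise SimConfigError(f"planted_effects: unknown gene {gene!r}")
            if ctype not in self.cell_types:
                raise SimConfigError(f"planted_effects: unknown cell_type {ctype!r}")
            if sample != "all" and sample not in samples:
                raise SimConfigError(f"planted_effects: unknown sample_id {sample!r}")


@dataclass
class GroundTruth:
    """Planted truth of a simulated dataset.

    ``planted_log2fc`` maps (gene, cell_type, sample_id) to the planted
    log2 fold change; ``true_interactions`` and ``decoy_interactions`` are
    (ligand, receptor, sender_type, receiver_type) tuples, the former
    referencing genes with planted positive effects in the stated sender
    and receiver types.
    """

    planted_log2fc: dict[tuple[str, str, str], float] = field(default_factory=dict)
    true_interactions: list[tuple[str, str, str, str]] = field(default_factory=list)
    decoy_interactions: list[tuple[str, str, str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_log2fc": {"|".join(k): v for k, v in self.planted_log2fc.items()},
                "true_interactions": self.true_interactions,
                "decoy_interactions": self.decoy_interactions,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            planted_log2fc={tuple(k.split("|")): v for k, v in d["planted_log2fc"].items()},
            true_interactions=[tuple(t) for t in d["true_interactions"]],
            decoy_interactions=[tuple(t) for t in d["decoy_interactions"]],
        )


def simulate_counts(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a count matrix with planted fold changes.

    Returns an :class:`anndata.AnnData` (cells x genes, integer counts in
    ``X``, annotation columns ``cell_type``, ``sample_id``, ``group_id`` in
    ``obs``) and the :class:`GroundTruth` of planted effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    n_genes = config.n_genes

    gene_means = config.baseline_mean * rng.lognormal(
        mean=0.0, sigma=config.gene_mean_log_sd, size=n_genes
    )

    # cell layout: every (sample, cell_type) stratum gets the same number of cells
    rows = []
    for gid, samples in config.groups.items():
        for sid in samples:
            for ctype in config.cell_types:
                for i in range(config.cells_per_type_per_sample):
                    rows.append((f"{sid}_{ctype}_{i:04d}", ctype, sid, gid))
    obs = pd.DataFrame(rows, columns=["cell_id", "cell_type", "sample_id", "group_id"])
    obs = obs.set_index("cell_id")
    n_cells = len(obs)

    spread = config.library_size_spread
    cell_scale = rng.lognormal(mean=-0.5 * spread**2, sigma=spread, size=n_cells)

    gene_index = {g: i for i, g in enumerate(genes)}
    lfc = np.zeros((n_genes, n_cells))
    gt = GroundTruth()
    ctype_arr = obs["cell_type"].to_numpy()
    sample_arr = obs["sample_id"].to_numpy()
    for gene, ctype, sample, l2 in config.planted_effects:
        targets = config.sample_ids() if sample == "all" else [sample]
        gi = gene_index[gene]
        for sid in targets:
            mask = (ctype_arr == ctype) & (sample_arr == sid)
            lfc[gi, mask] += l2
            key = (gene, ctype, sid)
            gt.planted_log2fc[key] = gt.planted_log2fc.get(key, 0.0) + l2

    mu = gene_means[:, None] * cell_scale[None, :] * np.exp2(lfc)
    size = config.dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(np.int64)

    # extra zeroing on top of NB sampling: dropout probability is logistic
    # (decreasing) in the log2 NB mean
    p_drop = expit(-config.dropout_slope * (np.log2(mu) - config.dropout_midpoint))
    counts[rng.random(counts.shape) < p_drop] = 0

    adata = ad.AnnData(
        X=counts.T,  # AnnData convention: cells x genes
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    adata.uns["sim_config"] = {
        k: v for k, v in dataclasses.asdict(config).items() if np.isscalar(v)
    }
    return adata, gt


# ---------------------------------------------------------------------------
# interaction prior
# ---------------------------------------------------------------------------


def simulate_interaction_prior(
    config: SimConfig,
    gt: GroundTruth,
    n_decoys: int,
    n_modeless: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build an OmniPath-style prior containing the planted true edges.

    The returned frame has the four columns ``ligand``, ``receptor``,
    ``directed`` (0/1), ``mode`` ("stimulation", "inhibition", or blank).
    ``n_decoys`` decoy edges are drawn between genes with no planted
    effect and appended to ``gt.decoy_interactions``; ``n_modeless`` extra
    edges are emitted with a missing mode so the loading filter has
    something to drop.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be nonnegative")
    if n_modeless < 0:
        raise ValueError("n_modeless must be nonnegative")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)

    planted_genes = {g for (g, _, _) in gt.planted_log2fc}
    free = [g for g in config.gene_names() if g not in planted_genes and not g.startswith("mt-")]
    used = {(l, r) for (l, r, *_ ) in gt.true_interactions}

    rows = [
        {"ligand": l, "receptor": r, "directed": 1, "mode": "stimulation"}
        for (l, r, _s, _t) in gt.true_interactions
    ]

    cell_types = list(config.cell_types)
    n_needed = n_decoys + n_modeless
    if n_needed > 0 and len(free) < 2:
        raise ValueError("not enough effect-free genes to draw decoy edges from")
    decoys: list[tuple[str, str]] = []
    while len(decoys) < n_needed:
        l, r = rng.choice(free, size=2, replace=False)
        if (l, r) in used:
            continue
        used.add((l, r))
        decoys.append((l, r))
    for i, (l, r) in enumerate(decoys):
        if i < n_decoys:
            sender, receiver = rng.choice(cell_types, size=2, replace=False)
            gt.decoy_interactions.append((l, r, str(sender), str(receiver)))
            rows.append({"ligand": l, "receptor": r, "directed": 1, "mode": "stimulation"})
        else:
            rows.append({"ligand": l, "receptor": r, "directed": 1, "mode": ""})
    return pd.DataFrame(rows, columns=["ligand", "receptor", "directed", "mode"])


# ---------------------------------------------------------------------------
# MxIF images
# ---------------------------------------------------------------------------


@dataclass
class Region:
    """A geometric region painted into one or more channels.

    ``shape`` is "rect" (params: row, col, height, width) or "ellipse"
    (params: row, col, r_radius, c_radius — center and semi-axes);
    ``intensities`` maps channel name -> painted intensity.
    """

    shape: str
    params: Mapping[str, float]
    intensities: Mapping[str, float]
    name: str = ""


@dataclass
class ImageConfig:
    height: int
    width: int
    channels: Sequence[str]
    regions: Sequence[Region] = ()
    background_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise SimConfigError("height and width must be positive")
        if len(set(self.channels)) != len(self.channels) or not self.channels:
            raise SimConfigError("channels must be nonempty and unique")
        if self.background_noise_sd < 0:
            raise SimConfigError("background_noise_sd must be nonnegative")
        for reg in self.regions:
            for ch in reg.intensities:
                if ch not in self.channels:
                    raise SimConfigError(f"regions: unknown channel {ch!r}")
            for v in reg.intensities.values():
                if v < 0:
                    raise SimConfigError("regions: intensities must be nonnegative")


@dataclass
class ImageGroundTruth:
    """Exact pixel sets painted per channel and per region."""

    channel_masks: dict[str, np.ndarray]
    region_masks: list[tuple[str, np.ndarray]]

    def expected_abundance(
        self,
        tumor_channel: str,
        marker_channels: Sequence[str],
        combine: str = "intersection",
    ) -> float:
        """Analytic normalized abundance: |overlayed marker mask ∩ tumor| / |tumor|."""
        tumor = self.channel_masks[tumor_channel]
        if not tumor.any():
            raise ValueError("tumor channel has no painted pixels")
        masks = [self.channel_masks[c] for c in marker_channels]
        caf = masks[0].copy()
        for m in masks[1:]:
            caf = caf & m if combine == "intersection" else caf | m
        return float((caf & tumor).sum() / tumor.sum())


def _region_mask(reg: Region, height: int, width: int) -> np.ndarray:
    mask = np.zeros((height, width), dtype=bool)
    p = reg.params
    if reg.shape == "rect":
        r0, c0 = int(p["row"]), int(p["col"])
        h, w = int(p["height"]), int(p["width"])
        if r0 < 0 or c0 < 0 or r0 + h > height or c0 + w > width:
            raise SimConfigError(f"region {reg.name!r} outside image bounds")
        mask[r0 : r0 + h, c0 : c0 + w] = True
    elif reg.shape == "ellipse":
        rr, cc = np.ogrid[:height, :width]
        d = ((rr - p["row"]) / p["r_radius"]) ** 2 + ((cc - p["col"]) / p["c_radius"]) ** 2
        mask[d <= 1.0] = True
        if p["row"] - p["r_radius"] < -0.5 or p["row"] + p["r_radius"] > height - 0.5:
            raise SimConfigError(f"region {reg.name!r} outside image bounds")
        if p["col"] - p["c_radius"] < -0.5 or p["col"] + p["c_radius"] > width - 0.5:
            raise SimConfigError(f"region {reg.name!r} outside image bounds")
    else:
        raise SimConfigError(f"unknown region shape {reg.shape!r}")
    if not mask.any():
        raise SimConfigError(f"region {reg.name!r} has zero area")
    return mask


def simulate_mxif_image(config: ImageConfig) -> tuple[np.ndarray, ImageGroundTruth]:
    """Paint regions into channels over Gaussian background noise.

    Returns a float32 array of shape (height, width, n_channels) and the
    ground truth of painted pixel sets.  Overlapping regions are allowed;
    a painted pixel takes the maximum intensity across regions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    img = np.zeros((h, w, len(config.channels)), dtype=np.float32)
    channel_index = {c: i for i, c in enumerate(config.channels)}
    channel_masks = {c: np.zeros((h, w), dtype=bool) for c in config.channels}
    region_masks: list[tuple[str, np.ndarray]] = []

    for reg in config.regions:
        mask = _region_mask(reg, h, w)
        region_masks.append((reg.name, mask))
        for ch, intensity in reg.intensities.items():
            ci = channel_index[ch]
            img[:, :, ci] = np.where(mask, np.maximum(img[:, :, ci], intensity), img[:, :, ci])
            if intensity > 0:
                channel_masks[ch] |= mask

    if config.background_noise_sd > 0:
        img += rng.normal(0.0, config.background_noise_sd, size=img.shape).astype(np.float32)
        np.clip(img, 0.0, None, out=img)
    return img, ImageGroundTruth(channel_masks=channel_masks, region_masks=region_masks)
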