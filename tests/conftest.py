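import anndata as ad
import numpy as np
import pandas as pd
import pytest

from tmekit.preprocess import normalize
from tmekit.de import de_by_celltype_sample
from tmekit.simulate import simulate_counts, simulate_interaction_prior
from tmekit.study import standard_study_config, STUDY_QC


def make_adata(counts: np.ndarray, genes, cells=None, obs=None) -> ad.AnnData:
    """AnnData from a gene x cell integer array (tests use the matrix view)."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    cells = cells if cells is not None else [f"c{i}" for i in range(n_cells)]
    adata = ad.AnnData(
        X=counts.T.astype(float),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(list(genes), name="gene_id")),
    )
    if obs is not None:
        for k, v in obs.items():
            adata.obs[k] = v
    return adata


@pytest.fixture(scope="session")
def study_data():
    """The standard synthetic communication study at full size, run once."""
    config, gt = standard_study_config(seed=11, cells_per_type_per_sample=500)
    counts, gt_counts = simulate_counts(config)
    gt.planted_log2fc = gt_counts.planted_log2fc
    prior = simulate_interaction_prior(config, gt, n_decoys=20, seed=12)
    return config, gt, counts, prior


@pytest.fixture(scope="session")
def study_de(study_data):
    """Pooled-family hurdle DE on the study's planted gene universe."""
    config, gt, counts, prior = study_data
    from tmekit.preprocess import filter_cells

    nm = normalize(filter_cells(counts, STUDY_QC))
    universe = sorted(set(prior["ligand"]) | set(prior["receptor"]))
    return de_by_celltype_sample(nm, universe)
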