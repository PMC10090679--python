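import numpy as np
import pandas as pd
import pytest

from esostrata import embedding as em
from esostrata import qc as qcmod
from esostrata import synthetic as syn


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study, QC'd, with truth labels aligned to cells."""
    res = syn.generate_dataset(syn.SynthSpec(seed=1))
    counts, report = qcmod.run_qc(res.counts, seed=1)
    truth = res.cell_truth.loc[counts.cell_ids]
    return {"raw": res, "counts": counts, "truth": truth, "report": report}


@pytest.fixture(scope="session")
def default_norm(default_dataset):
    return em.normalize_log10(default_dataset["counts"])


@pytest.fixture(scope="session")
def truth_clusters(default_dataset):
    """Truth populations encoded as integer cluster labels (sorted names)."""
    truth = default_dataset["truth"]
    names = sorted(truth["population"].unique())
    popmap = {p: i for i, p in enumerate(names)}
    labels = truth["population"].map(popmap).to_numpy()
    return {"labels": labels, "popmap": popmap, "inv": {i: p for p, i in popmap.items()}}


@pytest.fixture(scope="session")
def default_embedding(default_norm, default_dataset):
    """PCA scores and UMAP coordinates of the default dataset (seed 1)."""
    reg = em.regress_covariate(
        default_norm, default_dataset["counts"].cell_meta["replicate"].to_numpy()
    )
    pca = em.run_pca(reg, 50, seed=1)
    xy = em.run_umap(pca, seed=1)
    return {"pca": pca, "umap": xy}


def tiny_count_matrix(array, conditions=None, replicates=None):
    """Dense array -> CountMatrix with generated ids (test helper)."""
    from esostrata.io import CountMatrix

    arr = np.asarray(array)
    n, g = arr.shape
    cell_ids = np.array([f"c{i}" for i in range(n)], dtype=object)
    meta = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    if conditions is not None:
        meta["condition"] = conditions
    if replicates is not None:
        meta["replicate"] = replicates
    return CountMatrix(
        counts=arr,
        cell_ids=cell_ids,
        gene_ids=np.array([f"g{j}" for j in range(g)], dtype=object),
        cell_meta=meta,
    )
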