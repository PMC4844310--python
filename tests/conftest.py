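import numpy as np
import pandas as pd
import pytest

from graincoex.io import ExpressionExperiment


def build_experiment(accession, gene_values, groups, n_replicates=3,
                     noise=None, rng=None):
    """Assemble an in-memory experiment from per-gene group means.

    gene_values: {gene: [mean per group]}; groups: [(tissue, stage, genotype)].
    With ``noise`` and ``rng`` set, replicates get Gaussian jitter.
    """
    sample_rows, columns = [], []
    for gi, (tissue, stage, genotype) in enumerate(groups):
        for rep in range(1, n_replicates + 1):
            sid = f"s{gi}_{rep}"
            columns.append(sid)
            sample_rows.append({"sample_id": sid, "tissue": tissue,
                                "stage": stage, "genotype": genotype,
                                "replicate": rep})
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    from graincoex.io import parse_stage
    samples["stage_pos"] = [parse_stage(s) for s in samples["stage"]]

    data = {}
    for gene, means in gene_values.items():
        vals = []
        for gi in range(len(groups)):
            for _ in range(n_replicates):
                v = means[gi]
                if noise and rng is not None:
                    v += rng.normal(0, noise)
                vals.append(v)
        data[gene] = vals
    values = pd.DataFrame(data, index=columns).T
    return ExpressionExperiment(accession, values, samples)


@pytest.fixture
def tiny_experiment():
    """5 genes x 4 groups x 2 reps with assorted deterministic profiles."""
    rng = np.random.default_rng(42)
    groups = [("leaf", "vegetative", "wild type"),
              ("endosperm", "3-4 DAP", "wild type"),
              ("endosperm", "5-10 DAP", "wild type"),
              ("root", "vegetative", "wild type")]
    gene_values = {
        "g_peak": [4.0, 10.0, 7.0, 4.0],
        "g_peak2": [4.0, 9.5, 6.5, 4.0],
        "g_flat": [8.0, 8.0, 8.0, 8.0],
        "g_leaf": [10.0, 4.0, 4.0, 4.0],
        "g_late": [4.0, 5.0, 9.0, 4.0],
    }
    return build_experiment("TINY", gene_values, groups, n_replicates=2,
                            noise=0.05, rng=rng)


@pytest.fixture
def matrix_tsv(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text(
        "gene_id\ts1\ts2\n"
        "gA\t1.0\t2.0\n"
        "gB\t3.5\tNA\n"
        "gC\t2.25\t4.5\n"
    )
    return p


@pytest.fixture
def sheet_tsv(tmp_path):
    p = tmp_path / "s.tsv"
    p.write_text(
        "sample_id\ttissue\tstage\tgenotype\treplicate\n"
        "s1\tendosperm\t1 DAP\twild type\t1\n"
        "s2\tendosperm\t4 DAP\twild type\t1\n"
    )
    return p
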