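import numpy as np
import pandas as pd
import pytest

from rescuescreen import ExpressionStudy, SimulationDesign, generate_study

GROUPS = ("YC", "AC", "ST", "LT")


def make_study(values: np.ndarray, annotations=None) -> ExpressionStudy:
    """Wrap a genes x 24 array (6 per group, group-blocked columns) as a study."""
    n_genes, n_samples = values.shape
    n = n_samples // 4
    samples = [f"{g}_{j+1}" for g in GROUPS for j in range(n)]
    gene_ids = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    ann = None
    if annotations is not None:
        ann = pd.Series(annotations, index=gene_ids, name="annotation")
    return ExpressionStudy(
        values=pd.DataFrame(values, index=gene_ids, columns=samples),
        group_of=pd.Series([g for g in GROUPS for _ in range(n)], index=samples),
        annotations=ann,
    )


@pytest.fixture(scope="session")
def planted_run():
    """A 2000-gene planted study screened end to end (shared across tests)."""
    import rescuescreen as rs

    design = SimulationDesign(n_genes=2000, seed=1)
    study, truth = generate_study(design)
    filtered, report = rs.filter_present(study)
    stats_df = rs.screen_study(filtered)
    class_df = rs.classify(stats_df)
    merged = class_df.merge(truth.table, on="gene_id")
    return {
        "design": design, "study": study, "truth": truth,
        "filtered": filtered, "filter_report": report,
        "stats": stats_df, "classes": class_df, "merged": merged,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
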