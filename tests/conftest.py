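import numpy as np
import pandas as pd
import pytest

import lnclink as L

#: the four IR-vs-sham contrasts of the emulated design
IR_CONTRAST_KEYS = [("BALBc", 2), ("BALBc", 4), ("BALBc", 8), ("SPRET", 4)]


def ir_contrast(strain: str, week: float, p_cutoff: float = 0.05, fc_cutoff: float = 1.5) -> L.Contrast:
    return L.Contrast(
        name=f"{strain}_{week:g}w_IR_vs_sham",
        group_a={"strain": strain, "timepoint_weeks": week, "treatment": "sham"},
        group_b={"strain": strain, "timepoint_weeks": week, "treatment": "IR"},
        p_cutoff=p_cutoff,
        fc_cutoff=fc_cutoff,
    )


@pytest.fixture(scope="session")
def small_dataset() -> L.SimulatedDataset:
    """Desk-scale simulated dataset with planted DE and coupling."""
    return L.simulate_dataset(
        L.SimConfig(n_mrna=200, n_lnc=80, n_regulators=6, targets_per_regulator=3, seed=11)
    )


@pytest.fixture(scope="session")
def normalized_small(small_dataset):
    normed, _ = L.normalize(small_dataset.expression)
    return normed


@pytest.fixture()
def toy_matrix() -> L.ExpressionMatrix:
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
        index=pd.Index(["pA", "pB"], name="probe_id"),
        columns=["s1", "s2", "s3"],
    )
    return L.ExpressionMatrix(data, scale="linear")


def write_dataset(ds: L.SimulatedDataset, outdir) -> dict:
    """Write a simulated dataset in the on-disk dialects; return the paths."""
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "signature": outdir / "signature.txt",
    }
    L.write_expression_matrix(ds.expression, paths["expression"])
    L.write_sample_table(ds.samples, paths["samples"])
    L.write_probe_annotation(ds.annotation, paths["annotation"])
    L.write_gene_signature(ds.signature, paths["signature"])
    return {k: str(v) for k, v in paths.items()}


def pipeline_config(paths: dict, outdir, n_perms: int = 2000, seed: int = 17) -> dict:
    return {
        "inputs": paths,
        "contrasts": [
            {
                "name": f"{s}_{w:g}w_IR_vs_sham",
                "group_a": {"strain": s, "timepoint_weeks": w, "treatment": "sham"},
                "group_b": {"strain": s, "timepoint_weeks": w, "treatment": "IR"},
                "p_cutoff": 0.05,
                "fc_cutoff": 1.5,
            }
            for s, w in IR_CONTRAST_KEYS
        ],
        "permutation": {"n_perms": n_perms, "comparison": "abs_greater", "seed": seed},
        "thresholds": [5e-2, 5e-3, 5e-4],
        "output_dir": str(outdir),
    }
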