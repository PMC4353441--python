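"""Synthetic expression datasets with planted structure and truth tables.

The generator emulates the emulated study's design — 8 experimental
treatment groups (BALB/c sham/IR at 2, 4 and 8 weeks; SPRET/EiJ sham/IR at
4 weeks) with 3 biological replicates each, over a probe universe split
into lncRNA and mRNA classes — and plants three kinds of structure:

* strain effects: a fraction of probes shifted in every SPRET group;
* radiation responses: a fraction of probes shifted in one IR group
  (a specific strain and week), with random sign;
* lncRNA->mRNA coupling: each regulator lncRNA j carries a latent
  group-level factor z[j, g] ~ N(0, 1); the regulator and each of its
  targets add c * s * z[j, g] to their group-g log2 mean, where c is the
  coupling strength and s the coupling scale in log2 units.

Because replicate noise is iid N(0, sigma^2), the group mean carries noise
variance sigma^2 / n_reps and the population correlation of two coupled
group-mean vectors is c^2 s^2 / (c^2 s^2 + sigma^2 / n_reps) — analytically
controllable, which is why coupling operates at the group-mean level (the
correlation test consumes group means).  With the defaults (c = 1,
s = 1 log2, sigma = 0.25, 3 replicates) planted pairs have |r| ~ 0.98.

Coupled probes are drawn disjoint from DE-planted probes so the planted
correlation is not contaminated by shared deterministic response patterns.
Every planting is recorded in a truth table so each pipeline stage can be
scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    ProbeAnnotation,
    SampleTable,
    ValidationError,
    group_label,
)

#: the 8 experimental treatment groups: (strain, timepoint_weeks, treatment)
DESIGN = tuple(
    (strain, week, treatment)
    for strain, week in (("BALBc", 2), ("BALBc", 4), ("BALBc", 8), ("SPRET", 4))
    for treatment in ("sham", "IR")
)

#: the 4 IR-vs-sham contrasts a radiation response can be planted in
IR_CONTRASTS = tuple((s, w) for s, w, t in DESIGN if t == "IR")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the desk-scale study conditions."""

    n_mrna: int = 2000
    n_lnc: int = 800
    n_reps: int = 3
    frac_de: float = 0.1
    de_effect_log2: float = 2.0
    frac_strain_de: float = 0.05
    strain_effect_log2: float = 2.0
    n_regulators: int = 50
    targets_per_regulator: int = 5
    coupling_strength: float = 1.0  # c in [0, 1]
    coupling_scale_log2: float = 1.0  # s, log2 units
    noise_sd_log2: float = 0.25
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 1.5
    signature_frac: float = 0.2  # fraction of DE-planted mRNA symbols put in the signature
    frac_unannotated: float = 0.02  # probes with empty gene symbol
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_strain_de", "signature_frac", "frac_unannotated"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not 0 <= self.coupling_strength <= 1:
            raise ValidationError("coupling_strength must lie in [0, 1]")
        if min(self.n_mrna, self.n_lnc, self.n_reps) < 1:
            raise ValidationError("probe and replicate counts must be >= 1")
        if self.noise_sd_log2 <= 0:
            raise ValidationError("noise_sd_log2 must be > 0")
        if self.n_regulators * self.targets_per_regulator > self.n_mrna:
            raise ValidationError(
                "targets_per_regulator * n_regulators exceeds the mRNA universe"
            )
        if self.n_regulators > self.n_lnc:
            raise ValidationError("n_regulators exceeds the lncRNA universe")


@dataclass(frozen=True)
class TruthTable:
    """Simulator's record of planted structure.

    ``de_probes``: one row per planted radiation response or strain effect
    (probe_id, probe_class, contrast, strain, timepoint_weeks, direction,
    effect_log2).  ``coupled_pairs``: one row per planted (regulator
    lncRNA, target mRNA) pair with its coupling strength and expected
    population group-mean correlation.
    """

    de_probes: pd.DataFrame
    coupled_pairs: pd.DataFrame
    regulators: tuple = field(default_factory=tuple)


class SimulatedDataset(NamedTuple):
    expression: ExpressionMatrix  # linear scale
    samples: SampleTable
    annotation: ProbeAnnotation
    signature: GeneSet  # synthetic estrous-signature stand-in
    truth: TruthTable


def expected_coupling_correlation(cfg: SimConfig) -> float:
    """Closed-form population |r| of a coupled pair's group-mean vectors."""
    cs2 = (cfg.coupling_strength * cfg.coupling_scale_log2) ** 2
    sigma_group2 = cfg.noise_sd_log2**2 / cfg.n_reps
    return cs2 / (cs2 + sigma_group2)


def _design_samples(n_reps: int) -> SampleTable:
    rows = []
    for strain, week, treatment in DESIGN:
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{group_label(strain, week, treatment)}_r{rep}",
                    "strain": strain,
                    "timepoint_weeks": week,
                    "treatment": treatment,
                    "dose_cGy": 10.0 if treatment == "IR" else 0.0,
                    "replicate": rep,
                }
            )
    return SampleTable(pd.DataFrame(rows))


def simulate_dataset(cfg: SimConfig | None = None, **overrides) -> SimulatedDataset:
    """Generate one full synthetic dataset plus its truth table.

    Same seed, same config -> bit-identical outputs.  The returned matrix is
    linear-scale (2^log2), ready for the normalization stage.
    """
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)

    mrna_ids = [f"MRNA{i:05d}" for i in range(cfg.n_mrna)]
    lnc_ids = [f"LNC{i:05d}" for i in range(cfg.n_lnc)]
    probe_ids = mrna_ids + lnc_ids
    n_probes = len(probe_ids)
    classes = ["mRNA"] * cfg.n_mrna + ["lncRNA"] * cfg.n_lnc
    symbols = [f"Gene{i:05d}" for i in range(cfg.n_mrna)] + [
        f"Linc{i:05d}" for i in range(cfg.n_lnc)
    ]
    if cfg.frac_unannotated > 0:
        blank = rng.random(n_probes) < cfg.frac_unannotated
        symbols = ["" if b else s for s, b in zip(symbols, blank)]
    annotation = ProbeAnnotation(
        pd.DataFrame({"probe_id": probe_ids, "probe_class": classes, "gene_symbol": symbols})
    )
    samples = _design_samples(cfg.n_reps)
    group_order = samples.group_order()
    n_groups = len(group_order)
    idx_of = {p: i for i, p in enumerate(probe_ids)}

    # group-mean log2 expression, before replicate noise
    G = np.tile(
        rng.normal(cfg.baseline_mean_log2, cfg.baseline_sd_log2, n_probes)[:, None],
        (1, n_groups),
    )

    # --- coupling (drawn first; DE planting then avoids these probes) ---
    regulators = list(rng.choice(lnc_ids, size=cfg.n_regulators, replace=False))
    n_targets = cfg.n_regulators * cfg.targets_per_regulator
    targets = list(rng.choice(mrna_ids, size=n_targets, replace=False))
    pair_rows = []
    exp_r = expected_coupling_correlation(cfg)
    cs = cfg.coupling_strength * cfg.coupling_scale_log2
    for j, reg in enumerate(regulators):
        z = rng.standard_normal(n_groups)
        G[idx_of[reg]] += cs * z
        for t in targets[j * cfg.targets_per_regulator : (j + 1) * cfg.targets_per_regulator]:
            G[idx_of[t]] += cs * z
            pair_rows.append(
                {
                    "lnc_id": reg,
                    "mrna_id": t,
                    "coupling_strength": cfg.coupling_strength,
                    "expected_abs_r": exp_r,
                }
            )
    coupled = set(regulators) | set(targets)
    free = [p for p in probe_ids if p not in coupled]

    # --- planted radiation responses ---
    spret_cols = [i for i, g in enumerate(group_order) if g.startswith("SPRET")]
    de_rows = []
    n_de = int(round(cfg.frac_de * len(free)))
    de_probes = list(rng.choice(free, size=n_de, replace=False))
    for p in de_probes:
        strain, week = IR_CONTRASTS[rng.integers(len(IR_CONTRASTS))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        col = group_order.index(group_label(strain, week, "IR"))
        G[idx_of[p], col] += sign * cfg.de_effect_log2
        de_rows.append(
            {
                "probe_id": p,
                "probe_class": "mRNA" if p.startswith("MRNA") else "lncRNA",
                "contrast": f"{strain}_{week:g}w_IR_vs_sham",
                "strain": strain,
                "timepoint_weeks": week,
                "direction": "up" if sign > 0 else "down",
                "effect_log2": sign * cfg.de_effect_log2,
            }
        )

    # --- planted strain effects (all SPRET groups) ---
    remaining = [p for p in free if p not in set(de_probes)]
    n_strain = int(round(cfg.frac_strain_de * len(free)))
    n_strain = min(n_strain, len(remaining))
    for p in rng.choice(remaining, size=n_strain, replace=False):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        G[idx_of[p], spret_cols] += sign * cfg.strain_effect_log2
        de_rows.append(
            {
                "probe_id": p,
                "probe_class": "mRNA" if p.startswith("MRNA") else "lncRNA",
                "contrast": "strain_baseline",
                "strain": "SPRET",
                "timepoint_weeks": np.nan,
                "direction": "up" if sign > 0 else "down",
                "effect_log2": sign * cfg.strain_effect_log2,
            }
        )

    # --- replicates: group mean + iid noise; then back to linear scale ---
    sample_ids = samples.sample_ids
    group_col = {g: i for i, g in enumerate(group_order)}
    sample_group = samples.data.set_index("sample_id")["group"]
    log2_values = np.empty((n_probes, len(sample_ids)))
    for k, sid in enumerate(sample_ids):
        g = group_col[sample_group[sid]]
        log2_values[:, k] = G[:, g] + rng.normal(0.0, cfg.noise_sd_log2, n_probes)
    expression = ExpressionMatrix(
        pd.DataFrame(
            2.0**log2_values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
        ),
        scale="linear",
    )

    # --- synthetic estrous-signature stand-in ---
    de_mrna_symbols = sorted(
        {
            annotation.data.loc[r["probe_id"], "gene_symbol"]
            for r in de_rows
            if r["probe_class"] == "mRNA" and annotation.data.loc[r["probe_id"], "gene_symbol"]
        }
    )
    n_sig = int(round(cfg.signature_frac * len(de_mrna_symbols)))
    sig_symbols = (
        list(rng.choice(de_mrna_symbols, size=n_sig, replace=False)) if n_sig else []
    )
    signature = GeneSet.from_symbols(sig_symbols, name="synthetic_estrous")

    truth = TruthTable(
        de_probes=pd.DataFrame(
            de_rows,
            columns=[
                "probe_id",
                "probe_class",
                "contrast",
                "strain",
                "timepoint_weeks",
                "direction",
                "effect_log2",
            ],
        ),
        coupled_pairs=pd.DataFrame(
            pair_rows, columns=["lnc_id", "mrna_id", "coupling_strength", "expected_abs_r"]
        ),
        regulators=tuple(regulators),
    )
    return SimulatedDataset(expression, samples, annotation, signature, truth)


def simulate_pair(
    n_groups: int = 8,
    target_r: float = 0.0,
    noise_sd: float = 1.0,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two length-n vectors with population correlation ``target_r``.

    Bivariate-normal construction: y = r*x + sqrt(1 - r^2)*e with x, e iid
    N(0, noise_sd^2).  A unit-test fixture generator for the permutation
    machinery.
    """
    if abs(target_r) > 1:
        raise ValidationError("|target_r| must be <= 1")
    if n_groups < 3:
        raise ValidationError("n_groups must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, n_groups)
    e = rng.normal(0.0, noise_sd, n_groups)
    y = target_r * x + np.sqrt(1.0 - target_r**2) * e
    return x, y
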