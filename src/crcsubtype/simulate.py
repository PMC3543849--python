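"""Synthetic expression and drug-response data with planted subtype structure.

The generator emulates the statistical shape of RMA-normalized log2
microarray data: a nonnegative baseline around 7 log2 units with unit
Gaussian noise, on which a two-level subtype hierarchy is planted as
disjoint blocks of up-regulated probes — one block per type (shared by all
its subtypes) and one per subtype.  Matching drug-response tables plant a
subtype-specific sensitivity shift on the log10 EC50 scale.  Every stage of
the discovery pipeline is thereby testable against known ground truth
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .pharmacology import DrugResponseTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_hierarchical_expression",
    "generate_drug_response",
]

DEFAULT_HIERARCHY: dict[str, tuple[str, ...]] = {
    "1": ("1.1", "1.2", "1.3"),
    "2": ("2.1", "2.2"),
}


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-hierarchy generator.

    Defaults: 2 types split into 3 + 2 subtypes, 30 samples per subtype,
    5000 probes, 300-probe signature blocks per type and per subtype, a
    baseline of 7 log2 units with noise sd 1, and an up-shift of 2 log2
    units (a 4-fold change) on signature blocks.
    """

    samples_per_subtype: int = 30
    n_probes: int = 5000
    type_signature_size: int = 300
    subtype_signature_size: int = 300
    effect: float = 2.0          # log2 up-shift on planted blocks
    noise_sd: float = 1.0        # Gaussian noise sd, log2 units
    baseline_mean: float = 7.0   # log2 units
    hierarchy: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_HIERARCHY)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("effect must be nonnegative")
        if self.baseline_mean - 4 * self.noise_sd < 0:
            raise ValueError("baseline_mean - 4*noise_sd must be >= 0 to keep values nonnegative")
        n_types = len(self.hierarchy)
        n_subtypes = sum(len(v) for v in self.hierarchy.values())
        needed = n_types * self.type_signature_size + n_subtypes * self.subtype_signature_size
        if needed > self.n_probes:
            raise ValueError(
                f"signature blocks need {needed} probes but only {self.n_probes} available"
            )
        if self.samples_per_subtype < 1:
            raise ValueError("samples_per_subtype must be positive")

    @property
    def subtypes(self) -> list[str]:
        return [s for subs in self.hierarchy.values() for s in subs]


@dataclass
class SyntheticTruth:
    """Planted labels and signature blocks of a generated matrix."""

    sample_types: dict[str, str]
    sample_subtypes: dict[str, str]
    type_signatures: dict[str, list[str]]
    subtype_signatures: dict[str, list[str]]

    def to_frame(self) -> pd.DataFrame:
        samples = list(self.sample_types)
        return pd.DataFrame(
            {
                "type": [self.sample_types[s] for s in samples],
                "subtype": [self.sample_subtypes[s] for s in samples],
            },
            index=pd.Index(samples, name="sample_id"),
        )


def generate_hierarchical_expression(
    cfg: SyntheticConfig | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a log2 expression matrix with a planted two-level hierarchy.

    Baseline cells are Normal(baseline_mean, noise_sd^2) truncated at 0;
    each type's signature block is shifted +effect in that type's samples
    and each subtype's block +effect in that subtype's samples.  Blocks are
    disjoint.  Reproducible under the config seed.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    probes = [f"probe_{i:05d}" for i in range(cfg.n_probes)]

    samples: list[str] = []
    sample_types: dict[str, str] = {}
    sample_subtypes: dict[str, str] = {}
    for t, subs in cfg.hierarchy.items():
        for sub in subs:
            for i in range(cfg.samples_per_subtype):
                name = f"s{sub}_{i:03d}"
                samples.append(name)
                sample_types[name] = t
                sample_subtypes[name] = sub

    X = rng.normal(cfg.baseline_mean, cfg.noise_sd, (cfg.n_probes, len(samples)))
    np.clip(X, 0.0, None, out=X)

    cursor = 0
    type_sigs: dict[str, list[str]] = {}
    subtype_sigs: dict[str, list[str]] = {}
    for t in cfg.hierarchy:
        block = probes[cursor : cursor + cfg.type_signature_size]
        cursor += cfg.type_signature_size
        type_sigs[t] = block
        cols = [j for j, s in enumerate(samples) if sample_types[s] == t]
        rows = [int(p.split("_")[1]) for p in block]
        X[np.ix_(rows, cols)] += cfg.effect
    for sub in cfg.subtypes:
        block = probes[cursor : cursor + cfg.subtype_signature_size]
        cursor += cfg.subtype_signature_size
        subtype_sigs[sub] = block
        cols = [j for j, s in enumerate(samples) if sample_subtypes[s] == sub]
        rows = [int(p.split("_")[1]) for p in block]
        X[np.ix_(rows, cols)] += cfg.effect

    expr = ExpressionMatrix(pd.DataFrame(X, index=probes, columns=samples))
    truth = SyntheticTruth(
        sample_types=sample_types,
        sample_subtypes=sample_subtypes,
        type_signatures=type_sigs,
        subtype_signatures=subtype_sigs,
    )
    return expr, truth


def generate_drug_response(
    truth: SyntheticTruth,
    effects: Mapping[str, float],
    n_compounds_per_target: int = 3,
    noise_sd: float = 0.3,
    seed: int = 0,
    target: str = "TARGET1",
    baseline_log10_ec50: float = 0.0,
) -> DrugResponseTable:
    """Generate a potency table with a subtype-dependent sensitivity shift.

    For each cell line (one per truth sample) and compound,
    log10 EC50 = baseline - shift(subtype) + Normal(0, noise_sd^2); potency
    is 10 to that value, so larger shifts mean lower EC50 (more sensitive).
    ``effects`` maps subtype labels to shifts; unlisted subtypes shift 0.
    """
    unknown = set(effects) - set(truth.sample_subtypes.values())
    if unknown:
        raise ValueError(f"effects reference unknown subtypes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    lines = list(truth.sample_subtypes)
    compounds = [f"{target}_cpd{i + 1}" for i in range(n_compounds_per_target)]
    rows = np.empty((len(lines), len(compounds)))
    for i, line in enumerate(lines):
        shift = float(effects.get(truth.sample_subtypes[line], 0.0))
        rows[i] = 10.0 ** (
            baseline_log10_ec50 - shift + rng.normal(0.0, noise_sd, len(compounds))
        )
    potencies = pd.DataFrame(rows, index=pd.Index(lines, name="cell_line"), columns=compounds)
    return DrugResponseTable(
        potencies=potencies,
        log_base="10",
        targets={c: target for c in compounds},
    )
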