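"""FPKM-like case/control matrix generator with planted discriminative genes.

Background genes are i.i.d. log-normal and carry no class signal.
Informative genes shift the tumoral class's log-mean by a chosen number of
log-scale standard deviations, so a single threshold separates the classes
once the shift is large enough. Ground truth records every planted gene and
its achieved separation (AUC), which makes learner and engine behaviour
checkable without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from scipy.stats import rankdata

from camur.expression_io import ExpressionMatrix, write_matrix

LABEL_TUMORAL = "Tumoral"
LABEL_NORMAL = "Normal"

FIXTURE_NAMES = ("table1_toy", "chol_shape", "redundant6", "null60")


@dataclass(frozen=True)
class InformativeGroup:
    size: int
    shift: float      # in units of the background log-sigma
    direction: int = 1  # +1: up in tumoral, -1: down in tumoral

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("group size must be >= 1")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 60
    tumoral_fraction: float = 0.5
    n_genes: int = 20
    groups: tuple[InformativeGroup, ...] = ()
    log_mean: float = 2.0
    log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not (0.0 < self.tumoral_fraction < 1.0):
            raise ValueError("tumoral_fraction must be in (0, 1)")
        if self.n_genes < 1:
            raise ValueError("need at least 1 gene")
        if sum(g.size for g in self.groups) > self.n_genes:
            raise ValueError("informative group sizes exceed n_genes")
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be > 0")

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticSpec":
        groups = tuple(
            InformativeGroup(size=g["size"], shift=g["shift"],
                             direction=g.get("direction", 1))
            for g in doc.get("groups", ())
        )
        return cls(
            n_samples=doc.get("n_samples", 60),
            tumoral_fraction=doc.get("tumoral_fraction", 0.5),
            n_genes=doc.get("n_genes", 20),
            groups=groups,
            log_mean=doc.get("log_mean", 2.0),
            log_sigma=doc.get("log_sigma", 1.0),
            seed=doc.get("seed", 0),
        )


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    group: int
    direction: int
    separation: float  # empirical AUC of tumoral vs normal values


@dataclass
class GroundTruth:
    informative: list[PlantedGene] = field(default_factory=list)

    def gene_ids(self) -> list[str]:
        return [p.gene_id for p in self.informative]

    def as_dict(self) -> dict:
        return {
            "informative": [
                {"gene_id": p.gene_id, "group": p.group,
                 "direction": p.direction, "separation": p.separation}
                for p in self.informative
            ]
        }


def _auc(case: np.ndarray, control: np.ndarray) -> float:
    """Mann-Whitney AUC of case over control values."""
    ranks = rankdata(np.concatenate([case, control]))
    r_case = ranks[: case.size].sum()
    u = r_case - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * control.size))


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a labeled matrix and the ground truth of its planted genes."""
    rng = np.random.default_rng(spec.seed)
    n_tum = int(round(spec.tumoral_fraction * spec.n_samples))
    n_tum = min(max(n_tum, 1), spec.n_samples - 1)
    labels = [LABEL_TUMORAL] * n_tum + [LABEL_NORMAL] * (spec.n_samples - n_tum)
    tum = np.arange(spec.n_samples) < n_tum

    values = rng.lognormal(mean=spec.log_mean, sigma=spec.log_sigma,
                           size=(spec.n_samples, spec.n_genes))
    gene_ids = [f"G{j:05d}.1" for j in range(spec.n_genes)]
    sample_ids = [f"SAMP-{i:04d}" for i in range(spec.n_samples)]

    truth = GroundTruth()
    col = 0
    for group_no, group in enumerate(spec.groups):
        for _ in range(group.size):
            shifted_mean = spec.log_mean + group.direction * group.shift * spec.log_sigma
            values[tum, col] = rng.lognormal(mean=shifted_mean, sigma=spec.log_sigma,
                                             size=n_tum)
            sep = _auc(values[tum, col], values[~tum, col])
            truth.informative.append(PlantedGene(
                gene_id=gene_ids[col], group=group_no,
                direction=group.direction, separation=sep,
            ))
            col += 1

    m = ExpressionMatrix(sample_ids=sample_ids, gene_ids=gene_ids,
                         values=values, labels=labels,
                         sample_col_name="Sample", class_col_name="Class")
    return m, truth


def verify_plant(m: ExpressionMatrix, truth: GroundTruth) -> bool:
    """True when every informative gene separates the classes more strongly
    (|AUC - 0.5|) than every background gene."""
    tum = np.array([lab.casefold() == LABEL_TUMORAL.casefold() for lab in m.labels])
    informative = set(truth.gene_ids())
    info_sep, bg_sep = [], []
    for j, gene in enumerate(m.gene_ids):
        sep = abs(_auc(m.values[tum, j], m.values[~tum, j]) - 0.5)
        (info_sep if gene in informative else bg_sep).append(sep)
    if not info_sep:
        return True
    if not bg_sep:
        return True
    return min(info_sep) > max(bg_sep)


# --------------------------------------------------------------------------
# canonical fixtures

# 3x3 toy mirroring the documented input layout: sample ids, three gene
# columns, class in the last column.
_TABLE1_TOY = ExpressionMatrix(
    sample_ids=["TCGA-4G..", "TCGA-W5..", "TCGA-ZH.."],
    gene_ids=["ENSG00000130309.9", "ENSG00000101189.6", "ENSG00000260597.1"],
    values=np.array([
        [9.787, 2338.0, 0.141],
        [0.0323, 1.4725, 0.62107],
        [0.0622, 38.7757, 0.4818],
    ]),
    labels=["Tumoral", "Normal", "Tumoral"],
    sample_col_name="Aliquot",
    class_col_name="Class",
)


def table1_toy() -> ExpressionMatrix:
    return ExpressionMatrix(
        sample_ids=list(_TABLE1_TOY.sample_ids),
        gene_ids=list(_TABLE1_TOY.gene_ids),
        values=_TABLE1_TOY.values.copy(),
        labels=list(_TABLE1_TOY.labels),
        sample_col_name=_TABLE1_TOY.sample_col_name,
        class_col_name=_TABLE1_TOY.class_col_name,
    )


def fixture_spec(name: str, seed: int = 0) -> SyntheticSpec:
    if name == "chol_shape":
        # 45 samples, 36 tumoral / 9 normal, one strongly separating gene
        return SyntheticSpec(n_samples=45, tumoral_fraction=0.8, n_genes=20,
                             groups=(InformativeGroup(size=1, shift=6.0),),
                             seed=seed)
    if name == "redundant6":
        # six genes that each separate the classes on their own
        return SyntheticSpec(n_samples=60, tumoral_fraction=0.5, n_genes=26,
                             groups=tuple(InformativeGroup(size=1, shift=6.0)
                                          for _ in range(6)),
                             seed=seed)
    if name == "null60":
        return SyntheticSpec(n_samples=60, tumoral_fraction=0.5, n_genes=20,
                             groups=(), seed=seed)
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def make_fixture(name: str, out_dir: Union[str, Path], seed: int = 0) -> dict:
    """Write a canonical fixture CSV (and truth JSON) under ``out_dir``.

    Returns {"matrix": path, "truth": path-or-None}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{name}.csv"
    if name == "table1_toy":
        write_matrix(table1_toy(), csv_path)
        return {"matrix": csv_path, "truth": None}
    spec = fixture_spec(name, seed=seed)
    m, truth = generate_dataset(spec)
    if name in ("chol_shape", "redundant6") and not verify_plant(m, truth):
        raise RuntimeError(f"fixture {name} failed plant verification at seed {seed}")
    write_matrix(m, csv_path)
    truth_path = out_dir / f"{name}.truth.json"
    truth_path.write_text(json.dumps(truth.as_dict(), indent=2, sort_keys=True),
                          encoding="utf-8")
    return {"matrix": csv_path, "truth": truth_path}
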