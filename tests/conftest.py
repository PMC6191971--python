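import io

import numpy as np
import pytest

from camur.engine import EngineConfig, IterationRecord, RunResult, run_camur
from camur.expression_io import ExpressionMatrix, load_matrix
from camur.ripper import (
    Conjunction,
    LearnerParams,
    Literal,
    Metrics,
    RuleModel,
    evaluate_model,
)
from camur.synth import fixture_spec, generate_dataset, table1_toy

TABLE1_CSV = (
    "Aliquot,ENSG00000130309.9,ENSG00000101189.6,ENSG00000260597.1,Class\n"
    "TCGA-4G..,9.787,2338.0,0.141,Tumoral\n"
    "TCGA-W5..,0.0323,1.4725,0.62107,Normal\n"
    "TCGA-ZH..,0.0622,38.7757,0.4818,Tumoral\n"
)


@pytest.fixture
def table1_csv() -> str:
    return TABLE1_CSV


@pytest.fixture
def table1_matrix() -> ExpressionMatrix:
    return load_matrix(io.StringIO(TABLE1_CSV))


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    return table1_toy()


def make_matrix(values, labels, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ExpressionMatrix(
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        gene_ids=gene_ids or [f"g{j}" for j in range(g)],
        values=values,
        labels=list(labels),
    )


@pytest.fixture(scope="session")
def redundant6():
    m, truth = generate_dataset(fixture_spec("redundant6"))
    return m, truth


@pytest.fixture(scope="session")
def null60():
    m, truth = generate_dataset(fixture_spec("null60"))
    return m, truth


@pytest.fixture(scope="session")
def loose_run(redundant6) -> RunResult:
    m, _ = redundant6
    return run_camur(m, EngineConfig(mode="loose", seed=1))


@pytest.fixture(scope="session")
def strict_run(redundant6) -> RunResult:
    m, _ = redundant6
    return run_camur(m, EngineConfig(mode="strict", seed=1))


def model_from_genes(genes, positive="Tumoral", default="Normal",
                     threshold=1.0) -> RuleModel:
    """One single-conjunction model touching the given genes."""
    conj = Conjunction(tuple(Literal(g, "<", threshold) for g in genes))
    return RuleModel(positive_class=positive, default_class=default,
                     conjunctions=(conj,))


def record_for(model: RuleModel, matrix: ExpressionMatrix, index=1,
               eliminated=(), accepted=True) -> IterationRecord:
    metrics = evaluate_model(model, matrix)
    return IterationRecord(index=index, eliminated=tuple(sorted(eliminated)),
                           model=model, cv_metrics=metrics,
                           train_metrics=metrics, accepted=accepted)


def run_result_for(records, cfg=None, stop="combinations_exhausted") -> RunResult:
    return RunResult(config=cfg or EngineConfig(), records=list(records),
                     stop_reason=stop)
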