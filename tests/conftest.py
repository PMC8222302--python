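import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pniexpr.containers import ExpressionMatrix
from pniexpr.diffexpr import log_transform, moderated_t_table
from pniexpr.normalize import normalize_pipeline
from pniexpr.simulate import GeneratorConfig, generate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(values: np.ndarray, classes=None, probe_ids=None, sample_ids=None
                ) -> ExpressionMatrix:
    """Small-matrix factory for unit tests."""
    values = np.asarray(values)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"g{i + 1}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n_samples)]
    classes = classes or ["Endogenous"] * n_probes
    vals = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                        columns=sample_ids)
    return ExpressionMatrix(values=vals,
                            probe_classes=pd.Series(classes, index=vals.index))


def endogenous_only(matrix: ExpressionMatrix) -> ExpressionMatrix:
    endo = matrix.endogenous
    return ExpressionMatrix(values=endo,
                            probe_classes=matrix.probe_classes.loc[endo.index])


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (seed 1): matrix, annotation, truth."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    matrix, annotation, truth = default_cohort
    norm, factors = normalize_pipeline(matrix)
    return norm, factors, annotation, truth


@pytest.fixture(scope="session")
def main_deg_table(normalized_cohort):
    """EXT vs combined Focal/Non moderated-t table on the seed-1 cohort."""
    norm, _factors, annotation, _truth = normalized_cohort
    endo = endogenous_only(log_transform(norm))
    labels = annotation["cohort"].replace({"NON": "FOCAL_NON", "FOCAL": "FOCAL_NON"})
    return moderated_t_table(endo, labels, "FOCAL_NON", "EXT")
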