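import pytest
from hypothesis import settings

from greycast import load_builtin_dataset, load_plan_targets

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def builtin():
    return load_builtin_dataset()


@pytest.fixture(scope="session")
def plan_targets():
    return load_plan_targets()


# (a, b, C, P, level) as printed in the source yearbook analysis, used as
# the oracle for estimator and diagnostics tests.
PRINTED_MODELS = {
    "Medical institutions": (-0.0376, 19515.8506, 0.1535, 0.875, 2),
    "Medical beds": (-0.0273, 147551.9272, 0.0711, 1.000, 1),
    "Health technicians": (-0.0517, 152234.9888, 0.0497, 1.000, 1),
    "Licensed (assistant) physicians": (-0.0414, 65552.8446, 0.0522, 1.000, 1),
    "Registered nurses": (-0.0766, 57921.8695, 0.0562, 1.000, 1),
    "Pharmacists": (-0.0213, 7566.6949, 0.1531, 1.000, 1),
}

# Published 2025 (3-step-ahead) forecasts, nearest integer.
PRINTED_FORECASTS_2025 = {
    "Medical institutions": 28999,
    "Medical beds": 196328,
    "Health technicians": 262219,
    "Licensed (assistant) physicians": 101273,
    "Registered nurses": 129586,
    "Pharmacists": 9469,
}
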