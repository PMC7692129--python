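import warnings

import pytest

from eqapt.evaluation import evaluate_benchmark
from eqapt.fixtures import BENCHMARKS, table3_fixture


@pytest.fixture(scope="session")
def benchmark_results():
    """Evaluated results for all three reconstructed benchmark rounds."""
    out = {}
    for b in BENCHMARKS:
        bundle = table3_fixture(b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[b] = (
                bundle,
                evaluate_benchmark(
                    bundle.design,
                    bundle.reports,
                    bundle.statuses,
                    annotations=bundle.annotations,
                    mode=bundle.mode,
                ),
            )
    return out
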