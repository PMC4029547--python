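from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svunify.model import DeletionCall, GenomicInterval, TruthRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_call(contig: str, start: int, end: int, caller: str = "HC", **kw) -> DeletionCall:
    return DeletionCall(interval=GenomicInterval(contig, start, end), caller=caller, **kw)


def make_del(contig: str, start: int, end: int) -> TruthRecord:
    return TruthRecord(interval=GenomicInterval(contig, start, end), sv_type="DEL")


def random_instance(
    rng: np.random.Generator,
    n_calls: int,
    n_truths: int,
    span: int = 10_000,
    max_size: int = 400,
    contigs=("c1", "c2"),
):
    """A random call/truth instance for oracle-equivalence checks."""
    calls, truths = [], []
    for _ in range(n_calls):
        start = int(rng.integers(0, span))
        size = int(rng.integers(1, max_size))
        caller = str(rng.choice(["HC", "Pindel", "BD"]))
        calls.append(make_call(str(rng.choice(contigs)), start, start + size, caller))
    for _ in range(n_truths):
        start = int(rng.integers(0, span))
        size = int(rng.integers(1, max_size))
        truths.append(make_del(str(rng.choice(contigs)), start, start + size))
    return calls, truths


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
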