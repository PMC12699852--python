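import numpy as np
import pytest

from strscape.repeats import StrRecord, is_primitive


def brute_force_strs(
    seq: str,
    seq_id: str = "seq",
    min_length: int = 10,
    min_copies: int = 3,
    max_period: int = 9,
) -> set[StrRecord]:
    """Quadratic oracle: test every (start, period) pair by direct
    character comparison, independent of the production detector."""
    seq = seq.upper()
    n = len(seq)
    valid = [c in "ACGT" for c in seq]
    found: set[StrRecord] = set()
    for p in range(1, max_period + 1):
        for i in range(n - p):
            if not (valid[i] and valid[i + p]) or seq[i] != seq[i + p]:
                continue
            # left-maximality at period p
            if i > 0 and valid[i - 1] and valid[i - 1 + p] and seq[i - 1] == seq[i - 1 + p]:
                continue
            j = i
            while j + p < n and valid[j] and valid[j + p] and seq[j] == seq[j + p]:
                j += 1
            length = j - i + p
            copies = length // p
            unit = seq[i : i + p]
            if length < min_length or copies < min_copies:
                continue
            if not is_primitive(unit):
                continue
            found.add(StrRecord(seq_id, i, i + length, unit, p, copies))
    return found


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
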