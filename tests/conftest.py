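import pytest

from antnav.engine import Simulation
from antnav.scenarios import canonical


@pytest.fixture(scope="session")
def canonical_run():
    """Run a canonical scenario once per session and cache the result."""
    cache: dict[tuple[str, int], object] = {}

    def _run(name: str, seed: int = 1):
        key = (name, seed)
        if key not in cache:
            cache[key] = Simulation(canonical(name, seed), seed).run()
        return cache[key]

    return _run


def events_of(log):
    return {e for r in log.records for e in r["events"]}


def winner_sequence(log):
    seq = []
    for r in log.records:
        w = r["winner"]
        if not seq or seq[-1] != w:
            seq.append(w)
    return seq
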