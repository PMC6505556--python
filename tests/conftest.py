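import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from haltere import scenarios


@pytest.fixture(scope="session")
def scen():
    """Session-wide cache of full-scale scenario runs (deterministic)."""
    cache: dict = {}

    def run(name: str, omega: float | None = None, n_el: int | None = None):
        key = (name, omega, n_el)
        if key not in cache:
            spec = scenarios.scenario(name)
            if omega is not None:
                spec = spec.with_rotation(omega)
            cache[key] = scenarios.run_scenario(spec, n_el=n_el)
        return cache[key]

    return run
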