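import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for lp_oracle

from oleaflux import ToyModelSpec, build_toy_model

#: closed-form optima of the default toy parameterization (P/O 1.5,
#: 2 ATP/glc glycolysis, 12 NADPH/glc PPP, NGAM 5/glc, 2 ATP/citrate
#: export), derived by hand from the pathway balances:
#: max lipid flux at growth 0 and uptake U with forced citrate export
#: e = (84 U - 87 e) / 487; sole-source NADPH alternatives give
#: 7U/40 (transhydrogenase) and 7U/47 (mannitol cycle).
LIPID_PER_UPTAKE = 84.0 / 487.0
UPTAKE_PER_LIPID = 487.0 / 84.0
CITRATE_TERM = 87.0 / 487.0
TH_LIPID_PER_UPTAKE = 7.0 / 40.0
MANNITOL_LIPID_PER_UPTAKE = 7.0 / 47.0


@pytest.fixture(scope="session")
def toy_model():
    model, _ = build_toy_model(ToyModelSpec(), manifest=False)
    return model


@pytest.fixture(scope="session")
def toy_model_full():
    """Toy with every optional pathway switched on."""
    spec = ToyModelSpec(
        include_glycerol=True,
        include_fructose=True,
        include_sucrose=True,
        include_mannitol_cycle=True,
        include_transhydrogenase=True,
    )
    model, _ = build_toy_model(spec, manifest=False)
    return model


def lean_spec(**overrides) -> ToyModelSpec:
    """A reduced toy with few LP degrees of freedom, for enumeration tests."""
    base = dict(
        include_citrate_export=False,
        include_pyruvate_export=False,
        include_glycerol_valve=False,
    )
    base.update(overrides)
    return ToyModelSpec(**base)
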