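import numpy as np
import pytest

from ogeshift.charge_model import default_pka_table, ionizable_inventory, net_charge
from ogeshift.chem_core import STANDARD_RESIDUES
from ogeshift.oge_model import StripLayout

RESIDUES = sorted(STANDARD_RESIDUES)


@pytest.fixture
def layout() -> StripLayout:
    return StripLayout()


@pytest.fixture
def pka_table():
    return default_pka_table()


def random_peptide(rng: np.random.Generator, min_len: int = 6, max_len: int = 20) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(RESIDUES, size=length))


def grid_scan_pi(species, table=None, step: float = 1e-4) -> float:
    """Independent pI oracle: dense scan of the net-charge curve for its sign
    change, no root-finder involved."""
    inventory = ionizable_inventory(species, table)
    ph = np.arange(0.0, 14.0 + step, step)
    charge = net_charge(inventory, ph)
    idx = int(np.argmax(charge <= 0.0))  # first non-positive point
    if idx == 0:
        raise ValueError("charge curve does not cross zero on [0, 14]")
    return float((ph[idx - 1] + ph[idx]) / 2.0)
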