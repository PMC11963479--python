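"""Shared fixtures: packaged materials and the drying-scenario runs that
several test modules interrogate (run once per session)."""

from __future__ import annotations

import pytest

from rockroot.richards2d import build_domain, simulate
from rockroot.synthetic_data import default_material_params

DEFAULT_SEED = 1
T_END = 3600.0


@pytest.fixture(scope="session")
def materials():
    def _mats(rock: str, root: str = "root_stressed"):
        return {
            "soil": default_material_params("soil"),
            "rock": default_material_params(rock),
            "root": default_material_params(root),
        }

    return _mats


def _run(rock: str, contact: bool, materials, **kw):
    domain = build_domain(contact=contact, seed=DEFAULT_SEED)
    kw.setdefault("t_end", T_END)
    return simulate(domain, materials(rock), psi_init=0.0, psi_root=-1.5, **kw)


@pytest.fixture(scope="session")
def breccia_contact_run(materials):
    """Packaged Breccia scenario with direct root-rock contact."""
    return _run("breccia", True, materials)


@pytest.fixture(scope="session")
def breccia_nocontact_run(materials):
    return _run("breccia", False, materials)


@pytest.fixture(scope="session")
def dolostone_contact_run(materials):
    return _run("dolostone", True, materials)
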