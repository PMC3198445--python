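import numpy as np
import pytest

from mirkin.architectures import TranscrDegrArch, TranslInhibArch
from mirkin.kinetics import HillParams, TDParams, TIParams, predict_downstream
from mirkin.profiles import Condition, Kind, Profile, TimeGrid


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid()


def make_profile(mid, kind, cond, values) -> Profile:
    return Profile(
        molecule_id=mid,
        kind=kind,
        condition=cond,
        values=tuple(float(v) for v in values),
    )


@pytest.fixture(scope="session")
def dense_td_fixture(grid):
    """A transcription-degradation instance observed densely on the grid.

    Upstream: one declining miRNA, one transient repressor protein, one
    declining activator protein.  The downstream mRNA is the exact model
    trajectory at known parameters, evaluated at every grid point, so a fit
    is judged against data generated inside its own model class.
    """
    t = grid.array
    mirna = 900.0 * np.exp(-0.5 * t)
    repressor = 0.3 + 0.9 * np.exp(-0.5 * (t - 3.0) ** 2)
    activator = 1.6 * np.exp(-0.25 * t)
    params = TDParams(
        hill={"rep": HillParams(c=1, gamma=1.0), "act": HillParams(c=1, gamma=1.5)},
        k_transcr=350.0,
        k_react=4e-4,
        k_deg=0.3,
    )
    arch = TranscrDegrArch(
        gene="G", mirnas=("mirX",), rep_proteins=("rep",), act_proteins=("act",)
    )
    upstream = {"mirX": mirna, "rep": repressor, "act": activator}
    g0 = 300.0
    truth = predict_downstream(arch, params, upstream, grid, initial_value=g0, substeps=60)
    profiles = {}
    for cond in (Condition.WT, Condition.KO):
        profiles[("mirX", Kind.MIRNA, cond)] = make_profile("mirX", Kind.MIRNA, cond, mirna)
        profiles[("rep", Kind.PROTEIN, cond)] = make_profile("rep", Kind.PROTEIN, cond, repressor)
        profiles[("act", Kind.PROTEIN, cond)] = make_profile("act", Kind.PROTEIN, cond, activator)
        profiles[("G", Kind.MRNA, cond)] = make_profile("G", Kind.MRNA, cond, truth)
    return arch, params, upstream, profiles, truth
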