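import numpy as np
import pytest

from wntbead.types import Track


def build_track(
    n_minutes=10,
    cell_path=None,
    bead_path=None,
    membrane_path=None,
    in_contact=None,
    divided_at=None,
    cell_id="c0",
):
    """Construct a small Track from explicit or default geometry."""
    t = np.arange(n_minutes)
    if cell_path is None:
        cell_path = np.zeros((n_minutes, 2))
    cell_path = np.asarray(cell_path, dtype=float)
    if membrane_path is None:
        membrane_path = cell_path + np.array([10.0, 0.0])
    if in_contact is None:
        in_contact = np.ones(n_minutes, dtype=bool)
    in_contact = np.asarray(in_contact, dtype=bool)
    if bead_path is None:
        bead_path = cell_path + np.array([5.0, 0.0])
    bead_path = np.asarray(bead_path, dtype=float).copy()
    bead_path[~in_contact] = np.nan
    return Track(
        cell_id=cell_id,
        condition="WT",
        experiment_id="exp0",
        t=t,
        p_cell=cell_path,
        p_bead=bead_path,
        p_membrane=np.asarray(membrane_path, dtype=float),
        in_contact=in_contact,
        divided_at=divided_at,
    )


@pytest.fixture
def track_factory():
    return build_track
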