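import numpy as np
import pytest

from rhizotrace.plate_model import Polyline, RootAxis, RootSystem


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_tree(primary_len=10.0, laterals=((3.0, 2.0, 90.0), (6.0, 3.0, -90.0))):
    """Hand-built root system: vertical primary at x=0 from (0,0) down,
    straight laterals given as (branch_pos_mm, length_mm, signed angle deg
    from the primary's downward direction)."""
    import math

    axes = [RootAxis("p.000", 0, Polyline([(0.0, 0.0), (0.0, primary_len)]))]
    for i, (pos, length, ang) in enumerate(laterals, start=1):
        th = math.radians(ang)
        # primary direction is (0, 1); rotate by ang
        d = np.array([-math.sin(th), math.cos(th)])
        start = np.array([0.0, pos])
        axes.append(
            RootAxis(
                f"p.{i:03d}",
                1,
                Polyline(np.vstack([start, start + d * length])),
                parent_id="p.000",
                branch_pos_mm=pos,
            )
        )
    system = RootSystem("plantA", "P01", (0.0, 0.0), axes=axes)
    system.validate()
    return system


@pytest.fixture
def simple_tree():
    return make_tree()
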