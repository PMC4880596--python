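import numpy as np

from neuroplast.growth import ElementArray, GrowthCurveSpec


def make_elements(spec):
    """Build raw element arrays from {etype: [(neuron_id, z, connected), ...]}."""
    out = {}
    for etype, rows in spec.items():
        ids = np.array([r[0] for r in rows], dtype=np.int64)
        curve = GrowthCurveSpec("gaussian", nu=1e-4, eps=0.05)
        arr = ElementArray(etype, ids, [curve] * len(ids))
        arr.z = np.array([r[1] for r in rows], dtype=float)
        arr.connected = np.array([r[2] for r in rows], dtype=np.int64)
        out[etype] = arr
    return out
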