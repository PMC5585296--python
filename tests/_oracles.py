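"""Independent reference implementations shared by the test modules."""

import math

import numpy as np


def brute_force_q(x, y):
    """Literal double-loop evaluation of the event-synchronization index."""
    tx, ty = x.times, y.times

    def adj(t, i):
        ds = []
        if i + 1 < t.size:
            ds.append(t[i + 1] - t[i])
        if i >= 1:
            ds.append(t[i] - t[i - 1])
        return min(ds)

    c_xy = c_yx = 0.0
    for i in range(tx.size):
        for j in range(ty.size):
            tau = min(adj(tx, i), adj(ty, j)) / 2.0
            d = tx[i] - ty[j]
            if d == 0.0:
                c_xy += 0.5
                c_yx += 0.5
            elif 0 < d <= tau:
                c_xy += 1.0
            elif 0 < -d <= tau:
                c_yx += 1.0
    return (c_xy + c_yx) / math.sqrt(tx.size * ty.size)


def no_coincidence_pair(make_train):
    """Regular 1-s train vs tight doublets centered between its spikes.

    Doublet ISIs of 0.1 s force tau = 0.05 s while every cross distance is
    >= 0.45 s, so no quasi-coincidence exists anywhere and Q must be 0.
    """
    x = make_train(np.arange(1.0, 170.0, 1.0))
    base = np.arange(1.0, 169.0, 1.0)
    y = make_train(
        np.sort(np.concatenate([base + 0.45, base + 0.55])),
        unit_id="y", structure="NAc",
    )
    return x, y
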