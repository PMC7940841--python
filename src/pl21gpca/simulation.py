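"""Synthetic four-class expression matrix with planted block offsets.

The generator produces a 3000 x 80 matrix of i.i.d. uniform(0, 1) noise
and plants class structure by adding constant offsets to six sparse row
patterns restricted to the four 20-sample column blocks, then perturbs
every entry with zero-mean Gaussian noise of configurable variance.
The 80 samples thus fall into four classes of 20 (columns 1-20, 21-40,
41-60, 61-80 in 1-based terms), separated only through the 600 offset
rows; the remaining 2400 rows are pure noise.

Offset rules (1-based rows, i = 1..100):

====================  =============  ======
rows                  columns        offset
====================  =============  ======
i*30 - 29             1 - 20         +1
i*30 - 15             1 - 20         +1
i*30 - 19             21 - 40        +2
i*30 - 25             21 - 40        +2
i*30 - 9              41 - 60        +3
i*30 - 5              61 - 80        +4
====================  =============  ======

Gaussian noise is added unclipped by default; ``clip01=True`` clips the
final matrix to [0, 1] to emulate image-style noise injection, provided
for sensitivity checks only (clipping truncates the planted offsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

__all__ = ["SimulationSpec", "simulate", "OFFSET_PATTERNS"]

# (row offset within each 30-row period, class block index, added constant);
# 1-based rows i*30 - c for i = 1..100 become 0-based (i-1)*30 + (29 - c);
# class block b covers columns [b*20, (b+1)*20) at the default 80 samples.
OFFSET_PATTERNS: tuple[tuple[int, int, float], ...] = (
    (29 - 29, 0, 1.0),
    (29 - 15, 0, 1.0),
    (29 - 19, 1, 2.0),
    (29 - 25, 1, 2.0),
    (29 - 9, 2, 3.0),
    (29 - 5, 3, 4.0),
)


@dataclass
class SimulationSpec:
    """Parameters of the planted-offset simulation.

    ``noise_variance`` is the variance (sigma^2) of the additive
    Gaussian noise; the study grid is {0.4, 0.6, 0.8, 1.0, 1.2} but any
    nonnegative value is accepted.
    """

    n_genes: int = 3000
    n_samples: int = 80
    n_classes: int = 4
    noise_variance: float = 0.6
    clip01: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if self.n_samples % self.n_classes:
            raise ValueError("n_samples must be divisible by n_classes")


def simulate(
    spec: SimulationSpec | None = None, **kwargs
) -> tuple[NDArray[np.float64], NDArray[np.intp]]:
    """Generate the planted matrix and its class labels.

    Parameters may be given as a :class:`SimulationSpec` or as keyword
    arguments forwarded to it.

    Returns
    -------
    X : ndarray, (n_genes, n_samples)
        uniform base + block offsets + N(0, noise_variance) noise.
    labels : ndarray of int, (n_samples,)
        Class labels 1..4 (20 samples each at default size).
    """
    if spec is None:
        spec = SimulationSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimulationSpec or keyword arguments, not both")
    rng = np.random.default_rng(spec.seed)
    p, n = spec.n_genes, spec.n_samples
    X = rng.uniform(0.0, 1.0, size=(p, n))

    n_periods = max(1, p // 30)
    block = n // spec.n_classes
    for residue, b, const in OFFSET_PATTERNS:
        rows = np.arange(n_periods) * 30 + residue  # 0-based rows i*30 - c
        rows = rows[rows < p]
        X[np.ix_(rows, np.arange(b * block, (b + 1) * block))] += const

    if spec.noise_variance > 0:
        X += rng.normal(0.0, np.sqrt(spec.noise_variance), size=(p, n))
    if spec.clip01:
        np.clip(X, 0.0, 1.0, out=X)

    block = n // spec.n_classes
    labels = np.repeat(np.arange(1, spec.n_classes + 1), block)
    return X, labels
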