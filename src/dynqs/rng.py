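"""Reproducibility plumbing: one master seed, named independent substreams."""

from __future__ import annotations

import numpy as np

# Canonical substream names used across the package.  Splitting the master
# seed by name keeps e.g. offline-sample noise independent of particle
# initialization, so changing one component never perturbs another.
SUBSTREAMS = ("offline-noise", "pf-init", "pf-lambda", "pf-yxc", "pso", "minibatch")


def named_rngs(seed: int, names: tuple[str, ...] = SUBSTREAMS) -> dict[str, np.random.Generator]:
    """Split ``seed`` into independent named generators."""
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Generator for one named substream of ``seed``."""
    if name not in SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}; choose from {SUBSTREAMS}")
    return named_rngs(seed)[name]
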