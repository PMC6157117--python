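"""Seed-substream management.

A single master seed drives the whole experiment.  Each stochastic stage
(pedigree construction, gene dropping, phenotype generation, ...) receives an
independent generator derived from the master seed and a fixed stage label, so
re-running one stage never perturbs the random stream of another.
"""

from __future__ import annotations

import numpy as np

# Fixed labelled offsets; order is part of the reproducibility contract.
_STAGE_OFFSETS = {
    "pedigree": 1,
    "genotypes": 2,
    "phenotypes": 3,
    "replicate": 4,
    "experiment": 5,
}


def stage_rng(master_seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    """Return the generator for *stage* under *master_seed*.

    ``extra`` distinguishes replicate draws within one stage (e.g. Monte-Carlo
    repetitions that share a pedigree but redraw phenotypes).
    """
    if stage not in _STAGE_OFFSETS:
        raise KeyError(f"unknown rng stage {stage!r}; known: {sorted(_STAGE_OFFSETS)}")
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(_STAGE_OFFSETS[stage], int(extra)))
    return np.random.default_rng(ss)
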