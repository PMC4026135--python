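"""Random small instances shared by several test modules."""

import numpy as np
import pandas as pd

from riversed.reactions import Reaction, ReactionSet


def make_random_reaction_set(rng: np.random.Generator, n_reactions: int) -> ReactionSet:
    """Small random reaction set (<= 6 metabolites, <= 3 enzymes)."""
    mets = [f"M{i}" for i in range(6)]
    enzymes = [f"{1 + i}.{1 + i}.{1 + i}.{1 + i}" for i in range(3)]
    rxns = []
    for k in range(n_reactions):
        a, b = rng.choice(len(mets), size=2, replace=False)
        rxns.append(
            Reaction(
                f"R{k}",
                enzymes[int(rng.integers(len(enzymes)))],
                ((mets[int(a)], float(rng.integers(1, 4))),),
                ((mets[int(b)], float(rng.integers(1, 4))),),
                bool(rng.random() < 0.3),
            )
        )
    return ReactionSet(tuple(rxns))


def make_random_table(rng: np.random.Generator, n_samples: int, n_features: int,
                      prefix: str = "F") -> pd.DataFrame:
    return pd.DataFrame(
        rng.integers(0, 50, size=(n_samples, n_features)),
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"{prefix}{j}" for j in range(n_features)],
    )
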