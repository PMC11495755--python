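"""Small shared helpers: deterministic RNG derivation and column standardisation."""
from __future__ import annotations

import hashlib
import warnings

import numpy as np
import pandas as pd


def stable_hash(text: str) -> int:
    """Platform- and session-stable 63-bit hash of a string (SHA-256 based)."""
    return int.from_bytes(hashlib.sha256(text.encode("utf-8")).digest()[:8], "big") % (2**63)


def rng_for(seed: int, *tokens: object) -> np.random.Generator:
    """Derive an independent Generator from a base seed and a tuple of string tokens.

    The stream depends only on (seed, tokens), never on call order, so e.g. each
    simulated core gets a reproducible stream regardless of generation order.
    """
    keys = [int(seed) & (2**63 - 1)] + [stable_hash(str(t)) for t in tokens]
    return np.random.default_rng(keys)


def child_seed(seed: int, token: str) -> int:
    """A small (< 2**31) deterministic child seed for a named pipeline stage."""
    return (int(seed) ^ stable_hash(token)) % (2**31)


def zscore_columns(
    df: pd.DataFrame, ddof: int = 1, drop_constant: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each column; constant (zero-variance) columns are dropped with a warning.

    Returns the standardised frame and the list of dropped column names.
    """
    means = df.mean(axis=0)
    stds = df.std(axis=0, ddof=ddof)
    constant = stds <= 0.0
    dropped = list(df.columns[constant.to_numpy()])
    if dropped:
        if drop_constant:
            warnings.warn(
                f"dropping {len(dropped)} zero-variance column(s) before scaling",
                stacklevel=2,
            )
        else:
            raise ValueError(f"zero-variance columns present: {dropped[:5]}")
    kept = df.columns[~constant.to_numpy()]
    z = (df[kept] - means[kept]) / stds[kept]
    return z, dropped
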