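"""Deterministic labelled random streams.

All randomness in the package flows from a single integer root seed.
Child streams are derived by hashing string/integer labels into a
``SeedSequence`` spawn key, so adding a subject or a cohort to a study
never perturbs the streams of the ones that already exist.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(root: int, *labels: object) -> np.random.SeedSequence:
    """SeedSequence for the stream identified by ``labels`` under ``root``."""
    key = tuple(zlib.crc32(str(lab).encode("utf8")) for lab in labels)
    return np.random.SeedSequence(int(root), spawn_key=key)


def child_rng(root: int, *labels: object) -> np.random.Generator:
    """Generator for the labelled child stream."""
    return np.random.default_rng(child_seed(root, *labels))


def child_int(root: int, *labels: object) -> int:
    """A plain integer seed (< 2**31) derived from the labelled stream."""
    return int(child_seed(root, *labels).generate_state(1)[0] % (2**31))
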