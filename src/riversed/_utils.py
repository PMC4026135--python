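"""Shared helpers: error types, seeded substreams, logging."""

from __future__ import annotations

import logging
import zlib

import numpy as np

logger = logging.getLogger("riversed")


class RiversedError(Exception):
    """Base class for package errors."""


class InvalidDesignError(RiversedError):
    """Study design violates its invariants."""


class InfeasibleCoreError(RiversedError):
    """Requested sequencing depth cannot guarantee presence of all core taxa."""


class ReactionParseError(RiversedError):
    """Malformed reaction catalogue or pathway map file."""


class DegenerateInputError(RiversedError):
    """A statistic is undefined on this input (zero variance, singleton group, ...)."""


class PipelineStageError(RiversedError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent RNG for a named stage, derived from one root seed.

    Stage streams are decoupled by mixing a CRC32 of the stage name into the
    seed sequence, so adding draws in one stage never perturbs another.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def warn(msg: str) -> None:
    """Emit a machine-greppable warning on the package logger."""
    logger.warning("WARN: %s", msg)
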