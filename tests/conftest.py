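"""Shared fixtures: the toy heteroduplex design and small helper oracles."""

from __future__ import annotations

import numpy as np
import pytest

from sirnatrace.references import HeteroduplexModel, build_model, reverse_complement, toy_model


@pytest.fixture(scope="session")
def model() -> HeteroduplexModel:
    """The documented toy heteroduplex design (passes the design validator)."""
    return toy_model()


def make_model(
    target: str,
    sense_edits: dict[int, str] | None = None,
    anti_edits: dict[int, str] | None = None,
    feeding_fragment: tuple[int, int] | None = None,
    mismatch_area: tuple[int, int] | None = None,
) -> HeteroduplexModel:
    """Construct a small model by editing a target fragment positionwise."""
    if feeding_fragment is None:
        feeding_fragment = (0, len(target))
    f0, f1 = feeding_fragment
    frag = target[f0:f1]
    if mismatch_area is None:
        mismatch_area = (0, len(frag))
    sense = list(frag)
    anti = list(frag)
    for p, b in (sense_edits or {}).items():
        sense[p] = b
    for p, b in (anti_edits or {}).items():
        anti[p] = b
    return build_model(
        "".join(sense),
        reverse_complement("".join(anti)),
        target,
        feeding_fragment,
        mismatch_area,
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
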