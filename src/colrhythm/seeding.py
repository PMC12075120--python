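"""Named, independent seed streams derived from one master seed.

Wiring, background noise, stimulus-subset selection and
plasticity/shuffle randomness each get their own stream so that control
experiments can vary exactly one source of randomness at a time.
"""

from __future__ import annotations

import zlib

import numpy as np

STREAMS = ("wiring", "background", "stimulus", "plasticity")


def derive_seed(master: int, stream: str) -> int:
    """A deterministic 31-bit child seed for a named stream."""
    tag = zlib.crc32(stream.encode())
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(tag,))
    return int(ss.generate_state(1)[0] % (2**31))


def seed_table(master: int) -> dict[str, int]:
    return {s: derive_seed(master, s) for s in STREAMS}
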