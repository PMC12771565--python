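"""Deterministic seed derivation.

One master seed drives the whole pipeline; every stage draws its own seed
by stable hashing of (master, stage name).  Derived seeds stay below 2**31
so they are valid for every RNG the package touches (numpy Generators and
sklearn ``random_state`` integers alike).
"""

import hashlib


def derive_seed(master: int, *labels: object) -> int:
    """Derive a stage seed from a master seed and a label path.

    The mapping is a pure function of its arguments — independent of
    process, platform and PYTHONHASHSEED — so a single master seed fixes
    every random draw in a run.
    """
    key = ":".join([str(int(master))] + [str(l) for l in labels])
    digest = hashlib.blake2s(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
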