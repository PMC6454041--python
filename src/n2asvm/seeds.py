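"""Deterministic per-stage seed derivation from one master seed."""

import hashlib


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable stage seed: blake2b(master_seed, stage) reduced below 2**31."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)
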