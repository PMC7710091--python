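"""Small shared helpers: seed derivation and interval arithmetic."""

from __future__ import annotations

import hashlib


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage child seed from a master seed by stable hashing.

    Adding a new stage never perturbs the random streams of existing stages,
    and the result is below 2**31 so it is safe for any RNG constructor.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching 1-based inclusive intervals."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [ordered[0]]
    for start, end in ordered[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end + 1:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """At-least-1-bp overlap of two 1-based inclusive intervals."""
    return a[0] <= b[1] and b[0] <= a[1]
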