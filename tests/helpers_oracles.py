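"""Independent brute-force oracles, deliberately naive and separate from the package."""

from __future__ import annotations

import itertools
import math


def oracle_demand(design, capacity: int) -> dict[str, int]:
    """Count fragment uses by expanding the full construct×fragment incidence."""
    incidence = []
    for c in design.constructs.values():
        for fid in c.fragment_ids:
            incidence.append((c.construct_id, fid))
    plan = {}
    for fid in design.fragments:
        uses = sum(1 for _, f in incidence if f == fid)
        if uses:
            plan[fid] = math.ceil(uses / capacity)
    return plan


def oracle_feasible(design, status: dict[str, str]) -> set[str]:
    """Subset check, construct by construct."""
    ok = set()
    for c in design.constructs.values():
        verified = {f for f, s in status.items() if s == "verified"}
        if set(c.fragment_ids) <= verified:
            ok.add(c.construct_id)
    return ok


def oracle_merge(fragment_seqs: list[str], homology_bp: int, circular: bool) -> str:
    """Concatenate-and-deduplicate by scanning for the longest exact suffix/prefix
    match of at least ``homology_bp`` at each junction."""

    def longest_overlap(a: str, b: str) -> int:
        best = 0
        for k in range(homology_bp, min(len(a), len(b)) + 1):
            if a[-k:] == b[:k]:
                best = k
        return best

    merged = fragment_seqs[0]
    for nxt in fragment_seqs[1:]:
        ov = longest_overlap(merged, nxt)
        assert ov >= homology_bp, "oracle: junction without required overlap"
        merged = merged + nxt[ov:]
    if circular:
        ov = longest_overlap(merged, merged)
        # wrap junction: trailing copy of the first fragment's leading overlap
        k = longest_overlap(merged, fragment_seqs[0])
        assert k >= homology_bp
        merged = merged[: len(merged) - k]
    return merged


def oracle_thermocycler(temps: list[float], max_groups: int) -> float:
    """Minimal achievable max within-group span over all contiguous partitions
    of the sorted temperatures into at most ``max_groups`` groups."""
    ts = sorted(temps)
    n = len(ts)
    best = float("inf")
    k = min(max_groups, n)
    for g in range(1, k + 1):
        for cuts in itertools.combinations(range(1, n), g - 1):
            bounds = [0, *cuts, n]
            span = max(
                ts[bounds[i + 1] - 1] - ts[bounds[i]] for i in range(g)
            )
            best = min(best, span)
    return best
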