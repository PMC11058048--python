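"""Independent brute-force constructions used to cross-check the package."""

from __future__ import annotations


def frontier_oracle(points):
    """Efficiency frontier by greedy minimum-ICER construction.

    Start from the cheapest alternative and repeatedly step to the
    strictly-more-effective alternative with the smallest pairwise ICER
    (ties broken toward the larger QALY).  This is an independent
    characterisation of the increasing-ICER frontier; it does not share
    code with the removal-based implementation.

    Returns (frontier_names, classification) where classification maps
    every point to 'on_frontier' / 'dominated' / 'extendedly_dominated'.
    """
    pts = list(points)
    dominated = set()
    for p in pts:
        for q in pts:
            if q.name == p.name:
                continue
            if (q.total_cost <= p.total_cost and q.total_qaly >= p.total_qaly
                    and (q.total_cost < p.total_cost or q.total_qaly > p.total_qaly)):
                dominated.add(p.name)
                break
    live = [p for p in pts if p.name not in dominated]
    current = min(live, key=lambda p: (p.total_cost, -p.total_qaly, p.name))
    frontier = [current.name]
    while True:
        better = [p for p in live if p.total_qaly > current.total_qaly]
        if not better:
            break
        def icer(p):
            return (p.total_cost - current.total_cost) / (p.total_qaly - current.total_qaly)
        nxt = min(better, key=lambda p: (icer(p), -p.total_qaly, p.name))
        frontier.append(nxt.name)
        current = nxt
    classification = {}
    for p in pts:
        if p.name in frontier:
            classification[p.name] = "on_frontier"
        elif p.name in dominated:
            classification[p.name] = "dominated"
        else:
            classification[p.name] = "extendedly_dominated"
    return frontier, classification
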