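"""Independent oracles used by the test suite.

``brute_force_paths`` is a straight recursive enumeration of branch
sequences, deliberately sharing no code with the iterative stack-based
enumerator it checks.  ``cockcroft_gault`` recomputes renal clearance by
hand with float arithmetic for cross-checking the exact-decimal engine.
"""

from __future__ import annotations

from symptomcds.algorithm_model import DecisionAlgorithm, TerminalNode


def brute_force_paths(alg: DecisionAlgorithm) -> list[tuple[tuple[tuple[str, int], ...], str]]:
    """All (branch sequence, terminal) pairs, by naive recursion."""

    def rec(nid: str):
        node = alg.nodes[nid]
        if isinstance(node, TerminalNode):
            return [((), nid)]
        out = []
        for i, branch in enumerate(node.branches):
            for steps, term in rec(branch.target):
                out.append((((nid, i),) + steps, term))
        return out

    return rec(alg.root)


def cockcroft_gault(sex: str, age: float, weight: float, scr: float) -> float:
    """Hand-written clearance estimate (float arithmetic, rounded to 0.1)."""
    crcl = (140.0 - age) * weight / (72.0 * scr)
    if sex == "female":
        crcl *= 0.85
    return round(crcl, 1)
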