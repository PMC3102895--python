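"""Deliberately naive subsumption oracle.

Re-scans every completion rule over every class pair until nothing changes:
no worklist, no indexes, no sharing with :mod:`sdpkit.reasoner` beyond the
normal forms themselves.  Quadratic-and-worse on purpose — it exists to
cross-check the indexed saturation on small inputs, so it refuses anything
above a size guard.
"""

from __future__ import annotations

from .errors import SizeGuardError
from .model import BOT, TOP, EntityName, Ontology
from .normalize import normalize

MAX_DECLARED_NAMES = 60


def oracle_subsumptions(ont: Ontology) -> set[tuple[EntityName, EntityName]]:
    """Full entailed subsumption set over the declared class names.

    Returns every pair ``(A, B)`` with ``B ∈ S(A)``, ``A`` a declared class
    and ``B`` declared or ``owl:Thing``/``owl:Nothing``.
    """
    n_declared = len(ont.classes) + len(ont.roles)
    if n_declared > MAX_DECLARED_NAMES:
        raise SizeGuardError(
            f"oracle refuses {n_declared} declared names (> {MAX_DECLARED_NAMES})"
        )
    norm = normalize(ont)
    names = sorted(norm.class_names())
    roles = sorted(norm.role_names())

    # reflexive-transitive role closure, by repeated full scans
    inc = {(r, r) for r in roles} | set(norm.role_inclusions)
    changed = True
    while changed:
        changed = False
        for a, b in list(inc):
            for c, d in list(inc):
                if b == c and (a, d) not in inc:
                    inc.add((a, d))
                    changed = True

    S: dict[EntityName, set[EntityName]] = {a: {a, TOP} for a in names}
    R: dict[EntityName, set[tuple[EntityName, EntityName]]] = {r: set() for r in roles}

    changed = True
    while changed:
        changed = False
        for a in names:
            for a1, b in norm.atomic:  # R1
                if a1 in S[a] and b not in S[a]:
                    S[a].add(b)
                    changed = True
            for a1, a2, b in norm.conjunctive:  # R2
                if a1 in S[a] and a2 in S[a] and b not in S[a]:
                    S[a].add(b)
                    changed = True
            for a1, r, b in norm.exist_intro:  # R3
                if a1 in S[a] and (a, b) not in R[r]:
                    R[r].add((a, b))
                    changed = True
        for r in roles:
            for a, b in list(R[r]):
                for r2, b1, c in norm.exist_elim:  # R4
                    if r2 == r and b1 in S[b] and c not in S[a]:
                        S[a].add(c)
                        changed = True
                if BOT in S[b] and BOT not in S[a]:  # R5
                    S[a].add(BOT)
                    changed = True
        for r, s in inc:  # R6
            if r != s and not R[r] <= R[s]:
                R[s] |= R[r]
                changed = True
        for r in norm.transitive_roles:  # R7
            for a, b in list(R[r]):
                for b2, c in list(R[r]):
                    if b2 == b and (a, c) not in R[r]:
                        R[r].add((a, c))
                        changed = True

    keep = ont.classes | {TOP, BOT}
    return {
        (a, b) for a in ont.classes for b in S[a] if b in keep
    }
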