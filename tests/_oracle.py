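"""Straight-line re-implementation of the feedback loop, used as a fixed-point
oracle.  Written independently of the package internals: plain dicts, inline
weight arithmetic, no shared helpers beyond the input record type."""

import math


def straight_line_loop(psms, n_theoretical, pep_thr=0.95, prot_thr=0.95,
                       tol=1e-6, max_iter=100, cycles=1):
    """Return (q, status, selected, x, eliminated) after running the loop.

    ``psms`` are PSMRecord-likes; parent sets come from their assigned
    proteins; ``n_theoretical`` maps accession -> N_k.
    """
    parents = {}
    prob = {}
    sp_by_pep = {}
    max_sp = max(p.sp_score for p in psms)
    for p in psms:
        pep = p.peptide_sequence
        parents.setdefault(pep, set()).update(p.assigned_proteins)
        prob[pep] = max(prob.get(pep, 0.0), p.initial_probability)
        sp_by_pep.setdefault(pep, []).append(p.sp_score / max_sp)
    intensity = {pep: sum(v) for pep, v in sp_by_pep.items()}
    initial = dict(prob)
    x = dict(prob)

    def weights_for(sel, act):
        table = {}
        for pep in sorted(sel):
            pps = sorted(parents[pep] & act)
            if not pps:
                continue
            if len(pps) == 1:
                table[pep] = {pps[0]: 1.0}
                continue
            ip = intensity[pep]
            if ip <= 0:
                table[pep] = {k: 1.0 / len(pps) for k in pps}
                continue
            dist = {}
            for k in pps:
                sibs = sorted(
                    q
                    for q in sel
                    if q != pep and k in parents[q]
                )
                if not sibs:
                    dist[k] = 1.0
                else:
                    ib = sum(intensity[s] for s in sibs) / len(sibs)
                    dist[k] = abs(ip - ib) / ip
            raw = {
                k: sum(dist[j] for j in pps if j != k) / (len(pps) - 1)
                for k in pps
            }
            total = sum(raw.values())
            if total <= 0:
                table[pep] = {k: 1.0 / len(pps) for k in pps}
            else:
                table[pep] = {k: raw[k] / total for k in pps}
        return table

    q = {}
    hist = {}
    eliminated = set()
    prev_active = set()
    prev = (frozenset(), {}, frozenset())
    final_active = set()
    final_sel = set()
    for _ in range(max_iter):
        sel = {p for p in x if x[p] >= pep_thr and parents[p] - eliminated}
        act = set()
        for p in sel:
            act |= parents[p] - eliminated
        w1 = weights_for(sel, act)
        newq = {}
        for k in sorted(act):
            members = sorted(p for p in sel if k in parents[p])
            nk = len(members)
            Nk = max(n_theoretical.get(k, 0), nk, 1)
            qp = q[k] if k in prev_active else 1.0
            bracket = 1.0
            for p in members:
                bracket *= 1.0 - x[p] * w1[p][k] * qp
            bracket = min(max(1.0 - bracket, 0.0), 1.0)
            if nk == 0:
                newq[k] = 0.0
            elif nk == Nk:
                newq[k] = 1.0 if bracket > 0 else 0.0
            elif bracket == 0.0:
                newq[k] = 0.0
            else:
                newq[k] = min(max(bracket ** (-math.log(nk / Nk)), 0.0), 1.0)
        q.update(newq)  # last computed q sticks, even if eliminated this round
        for k in set(hist) | act:
            if k in eliminated:
                continue
            hist.setdefault(k, []).append("in" if k in act else "out")
        high = {k for k in act if newq[k] >= prot_thr}
        sel2 = set(sel)
        for p in parents:
            if p not in sel2 and parents[p] & high:
                sel2.add(p)

        def recompute(sel2, act, newq):
            w2 = weights_for(sel2, act)
            x2 = {}
            kept = set()
            for p in sorted(sel2):
                if p not in w2:
                    continue
                kept.add(p)
                x2[p] = min(
                    max(sum(w * newq[k] for k, w in sorted(w2[p].items())), 0.0),
                    1.0,
                )
            return w2, x2, kept

        w2, x2, sel2 = recompute(sel2, act, newq)
        newly = []
        for k in sorted(hist):
            if k in eliminated:
                continue
            h = hist[k]
            reentries = sum(
                1 for t in range(1, len(h)) if h[t - 1] == "out" and h[t] == "in"
            )
            if reentries >= cycles:
                newly.append(k)
        if newly:
            eliminated.update(newly)
            act -= set(newly)
            for k in newly:
                newq.pop(k, None)
            w2, x2, sel2 = recompute(sel2, act, newq)
        for p, v in x2.items():
            x[p] = v
        cur = (frozenset(act), dict(newq), frozenset(sel2))
        done = (
            cur[0] == prev[0]
            and cur[2] == prev[2]
            and all(abs(cur[1][k] - prev[1][k]) < tol for k in cur[0])
        )
        prev = cur
        prev_active = set(act)
        final_active, final_sel = set(act), set(sel2)
        if done:
            break
    for p in parents:
        if parents[p] and not (parents[p] - eliminated):
            x[p] = initial[p]
            final_sel.discard(p)
    status = {}
    ever = set(hist) | eliminated
    for k in ever:
        if k in eliminated:
            status[k] = "eliminated"
        elif k in final_active:
            status[k] = "active"
        else:
            status[k] = "dropped"
    return q, status, final_sel, x, eliminated
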