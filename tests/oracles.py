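"""Independent brute-force reference implementations for oracle tests.

Everything here is written as plain per-gene / per-row Python loops over
dicts, deliberately sharing no code or vectorized shortcuts with the package,
so that agreement is evidence and not tautology.
"""

from __future__ import annotations


def oracle_best_hit_per_query(rows):
    """rows: iterable of (query, subject, bitscore, evalue) -> {query: subject}."""
    per_pair = {}
    for q, s, bits, ev in rows:
        key = (q, s)
        if key not in per_pair:
            per_pair[key] = (bits, ev)
        else:
            old_bits, old_ev = per_pair[key]
            if bits > old_bits or (bits == old_bits and ev < old_ev):
                per_pair[key] = (bits, ev)
    best = {}
    for (q, s), (bits, ev) in per_pair.items():
        incumbent = best.get(q)
        if incumbent is None:
            best[q] = (s, bits, ev)
            continue
        s0, b0, e0 = incumbent
        if (bits, -ev) > (b0, -e0) or (bits == b0 and ev == e0 and s < s0):
            best[q] = (s, bits, ev)
    return {q: s for q, (s, _, _) in best.items()}


def oracle_rbh(rows_ab, rows_ba):
    """Reciprocal best hits as a set of (a, b) pairs."""
    best_ab = oracle_best_hit_per_query(rows_ab)
    best_ba = oracle_best_hit_per_query(rows_ba)
    pairs = set()
    for a, b in best_ab.items():
        if best_ba.get(b) == a:
            pairs.add((a, b))
    return pairs


def oracle_classify_regulatory(gene_ids, hit_rows, tf_set, sig_set, evalue_max):
    """hit_rows: (gene, accession, evalue); accessions compared without version.

    Returns {gene: reason} over the full catalog.
    """

    def bare(acc):
        head, _, tail = acc.rpartition(".")
        return head if head and tail.isdigit() else acc

    tf_bare = {bare(a) for a in tf_set}
    sig_bare = {bare(a) for a in sig_set}
    reasons = {}
    for g in gene_ids:
        is_tf = is_sig = False
        for gene, acc, ev in hit_rows:
            if gene != g or ev > evalue_max:
                continue
            if bare(acc) in tf_bare:
                is_tf = True
            if bare(acc) in sig_bare:
                is_sig = True
        if is_tf and is_sig:
            reasons[g] = "both"
        elif is_tf:
            reasons[g] = "tf"
        elif is_sig:
            reasons[g] = "signaling"
        else:
            reasons[g] = "none"
    return reasons


def oracle_call_lineages(averages, cluster_to_lineage, lineages, threshold):
    """averages: {gene: {cluster: value}} -> {gene: (lineage_set, category)}.

    Representative cluster per lineage = highest average, ties to the lowest
    cluster id numerically; expressed iff strictly above threshold.
    """

    def ckey(c):
        return (0, int(c)) if str(c).isdigit() else (1, str(c))

    out = {}
    for gene, values in averages.items():
        expressed = set()
        for lin in lineages:
            members = sorted(
                (c for c, l in cluster_to_lineage.items() if l == lin), key=ckey
            )
            members = [c for c in members if c in values]
            if not members:
                continue
            rep, rep_val = None, None
            for c in members:
                if rep_val is None or values[c] > rep_val:
                    rep, rep_val = c, values[c]
            if rep_val > threshold:
                expressed.add(lin)
        n = len(expressed)
        if n == 0:
            cat = "undetected"
        elif n == len(lineages):
            cat = "ubiquitous"
        else:
            cat = "restricted"
        out[gene] = (frozenset(expressed), cat)
    return out


def oracle_call_onset(trajectory, hours, expr_threshold, maternal_threshold, t0_max):
    """trajectory: {hour: fpkm} -> (origin, onset or None)."""
    detected = any(trajectory[h] > expr_threshold for h in hours)
    if not detected:
        return "undetected", None
    t0 = trajectory[0]
    if t0 > maternal_threshold:
        return "maternal", None
    if t0 < t0_max:
        for h in hours:
            if trajectory[h] > expr_threshold:
                if h >= 6:
                    return "zygotic_clear", h
                break
    return "ambiguous_t0", None


def oracle_dip_rise(trajectory, hours, window, expr_threshold):
    """Dip-then-rise onset for a maternal trajectory, or None."""
    t_min, v_min = None, None
    for h in window:
        if h in trajectory and (v_min is None or trajectory[h] < v_min):
            t_min, v_min = h, trajectory[h]
    if v_min is None or not v_min < trajectory[0]:
        return None
    for h in hours:
        if h > t_min and trajectory[h] > v_min and trajectory[h] > expr_threshold:
            return h
    return None


def oracle_coexpression(cell_values_a, cell_values_b, expressed_min):
    """Parallel per-cell value lists -> (n_a, n_b, n_both, fraction)."""
    n_a = n_b = n_both = 0
    for va, vb in zip(cell_values_a, cell_values_b):
        ea, eb = va > expressed_min, vb > expressed_min
        n_a += ea
        n_b += eb
        n_both += ea and eb
    n = len(cell_values_a)
    return n_a, n_b, n_both, n_both / n
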