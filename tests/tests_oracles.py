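"""Independent brute-force scorers used as oracles by the test suite."""

import math

from genenorm.normalizer import name_tokens


def brute_force_bow_rank(mention, entries, threshold):
    """Recompute IDF-style weights and cosine from scratch against every
    name of every entry; independent of the indexed implementation."""
    df = {}
    per_entry_tokens = {}
    for e in entries:
        toks = set()
        for n in e.names:
            toks |= set(name_tokens(n))
        per_entry_tokens[e.gene_id] = [set(name_tokens(n)) for n in e.names]
        for t in toks:
            df[t] = df.get(t, 0) + 1
    N = len(entries)

    def w(t):
        return math.log(1 + N / df[t]) if t in df else math.log(1 + N)

    m_toks = set(name_tokens(mention))
    if not m_toks:
        return []
    m_norm = math.sqrt(sum(w(t) ** 2 for t in m_toks))
    out = []
    for e in entries:
        best = 0.0
        for n_toks in per_entry_tokens[e.gene_id]:
            shared = m_toks & n_toks
            if not shared or not n_toks:
                continue
            n_norm = math.sqrt(sum(w(t) ** 2 for t in n_toks))
            best = max(best, sum(w(t) ** 2 for t in shared)
                       / (m_norm * n_norm))
        if best >= threshold:
            out.append((e.gene_id, best))
    out.sort(key=lambda x: (-x[1], (0, int(x[0])) if x[0].isdigit()
                            else (1, x[0])))
    return out
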