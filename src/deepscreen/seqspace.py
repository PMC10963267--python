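"""Sequence encodings, PCA projection and mutant-pool construction.

Amino acids are indexed alphabetically over the 20 standard one-letter codes,
followed by '*' (stop) and 'X' (unknown); each index is written as a 5-bit
most-significant-first binary block, so alanine is [0,0,0,0,0] and glycine
(index 5) is [0,0,1,0,1].  The compressed encoding keeps PCA inputs dense
while still distinguishing every residue.

Mutant pools mirror the two selection arms of ML-guided affinity maturation:
a random arm (all single mutants plus up to 1,000 sampled mutants per edit
distance 2-5 per seed) and an ML arm (candidates scored by a classifier,
filtered at high-hit probability >= 0.9, sampled per edit distance 2-5 and
excluding anything already in the random arm).
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "*X"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
BITS_PER_RESIDUE = 5


def encode_onehot5(seq: str) -> np.ndarray:
    """Encode a sequence as concatenated 5-bit binary blocks (MSB first)."""
    bits = np.zeros(BITS_PER_RESIDUE * len(seq), dtype=np.uint8)
    for pos, aa in enumerate(seq):
        try:
            idx = _INDEX[aa]
        except KeyError:
            raise ValueError(f"unsupported character {aa!r} at position {pos}") from None
        for b in range(BITS_PER_RESIDUE):
            bits[pos * BITS_PER_RESIDUE + b] = (idx >> (BITS_PER_RESIDUE - 1 - b)) & 1
    return bits


def decode_onehot5(bits) -> str:
    """Inverse of :func:`encode_onehot5`."""
    bits = np.asarray(bits, dtype=int)
    if bits.size % BITS_PER_RESIDUE:
        raise ValueError("bit vector length must be a multiple of 5")
    out = []
    for block in bits.reshape(-1, BITS_PER_RESIDUE):
        idx = int("".join(map(str, block)), 2)
        if idx >= len(ALPHABET):
            raise ValueError(f"5-bit block decodes to {idx}, outside the alphabet")
        out.append(ALPHABET[idx])
    return "".join(out)


def encode_matrix(seqs: Iterable[str]) -> np.ndarray:
    return np.vstack([encode_onehot5(s) for s in seqs]).astype(float)


def pca_project(encodings: np.ndarray, return_model: bool = False):
    """Scores on the first two principal axes of the mean-centred encodings."""
    encodings = np.asarray(encodings, dtype=float)
    if encodings.shape[0] < 3:
        raise ValueError("need at least 3 rows for a PCA projection")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(encodings)
    if np.allclose(pca.explained_variance_, 0):
        coords = np.zeros_like(coords)
    return (coords, pca) if return_model else coords


def edit_distance(a: str, b: str) -> int:
    """Hamming distance between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y)


def count_mutants(length: int, order: int) -> int:
    """Closed form C(L, k) * 19^k for exact-Hamming-distance-k mutants."""
    from math import comb
    return comb(length, order) * 19 ** order


def enumerate_mutants(seed: str, order: int, cap: int | None = None,
                      rng_seed: int | None = None) -> list:
    """All (or a seeded sample of) sequences at exact Hamming distance ``order``.

    Orders 1-3 are enumerated exhaustively in deterministic (position, residue)
    order and truncated at ``cap`` if set.  Orders 4-5 are sampled uniformly
    without replacement up to ``cap`` (required), since exhaustive enumeration
    is astronomically large.  The seed itself is never emitted.
    """
    if not 1 <= order <= 5:
        raise ValueError("order must be in 1..5")
    if cap is not None and cap < 1:
        raise ValueError("cap must be >= 1")
    L = len(seed)
    if order > L:
        return []
    if order <= 3:
        out = []
        for positions in itertools.combinations(range(L), order):
            alts = [[aa for aa in AA20 if aa != seed[p]] for p in positions]
            for combo in itertools.product(*alts):
                s = list(seed)
                for p, aa in zip(positions, combo):
                    s[p] = aa
                out.append("".join(s))
                if cap is not None and len(out) >= cap:
                    return out
        return out
    if cap is None:
        raise ValueError("a cap is required for orders 4 and 5")
    rng = np.random.default_rng(rng_seed)
    total = count_mutants(L, order)
    target = min(cap, total)
    seen: set = set()
    out = []
    aa_arr = np.array(list(AA20))
    while len(out) < target:
        positions = rng.choice(L, size=order, replace=False)
        s = list(seed)
        for p in positions:
            alts = aa_arr[aa_arr != seed[p]]
            s[p] = str(rng.choice(alts))
        cand = "".join(s)
        if cand not in seen:
            seen.add(cand)
            out.append(cand)
    return out


def _sample_order(seed: str, order: int, cap: int, rng: np.random.Generator) -> list:
    """Up to ``cap`` distinct mutants at exact distance ``order`` (uniform)."""
    if cap <= 0:
        return []
    total = count_mutants(len(seed), order)
    if order <= 3 and total <= max(4 * cap, 10000):
        pool = enumerate_mutants(seed, order)
        if len(pool) <= cap:
            return pool
        idx = rng.choice(len(pool), size=cap, replace=False)
        return [pool[i] for i in sorted(idx)]
    return enumerate_mutants(seed, order, cap=cap,
                             rng_seed=int(rng.integers(0, 2 ** 31)))


def select_random_pool(seeds, per_order_cap: int = 1000, rng_seed: int = 0,
                       order_caps: dict | None = None) -> pd.DataFrame:
    """The random mutagenesis arm: all singles + sampled orders 2-5 per seed.

    Duplicates across seeds are removed first-seed-wins, so the pool size is
    at most ``n_seeds * (singles + 4 * cap)``.
    """
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("seed sequences must be distinct")
    rng = np.random.default_rng(rng_seed)
    caps = {k: per_order_cap for k in (2, 3, 4, 5)}
    if order_caps:
        caps.update(order_caps)
    rows = []
    chosen: set = set(seeds)
    for si, seed in enumerate(seeds):
        for order in (1, 2, 3, 4, 5):
            muts = (enumerate_mutants(seed, 1) if order == 1
                    else _sample_order(seed, order, caps[order], rng))
            for m in muts:
                if m in chosen:
                    continue
                chosen.add(m)
                rows.append((f"seed{si}", m, order, "random", np.nan))
    return pd.DataFrame(rows, columns=["seed_id", "sequence", "edit_distance",
                                       "provenance", "score"])


def select_ml_pool(seeds, scored_mutants, score_min: float = 0.9,
                   exclusion: set | None = None, per_order_cap: int = 1000,
                   rng_seed: int = 0) -> pd.DataFrame:
    """The ML-guided arm: score-filtered candidates sampled per edit distance.

    ``scored_mutants`` is an iterable of (sequence, score) with scores in
    [0, 1] (the classifier's high-hit probability).  Candidates scoring below
    ``score_min``, present in ``exclusion`` (typically the random arm), or
    outside edit distances 2-5 from their nearest seed are removed; up to
    ``per_order_cap`` survivors are sampled per seed per distance.
    """
    seeds = list(seeds)
    exclusion = set(exclusion or ())
    rng = np.random.default_rng(rng_seed)
    buckets: dict = {}
    seen: set = set()
    for seq, score in scored_mutants:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [0, 1]")
        if score < score_min or seq in exclusion or seq in seen or seq in seeds:
            continue
        seen.add(seq)
        dists = [(edit_distance(seq, s), i) for i, s in enumerate(seeds)
                 if len(s) == len(seq)]
        if not dists:
            continue
        d, si = min(dists)
        if not 2 <= d <= 5:
            continue
        buckets.setdefault((si, d), []).append((seq, score))
    rows = []
    for (si, d), cands in sorted(buckets.items()):
        if len(cands) > per_order_cap:
            idx = rng.choice(len(cands), size=per_order_cap, replace=False)
            cands = [cands[i] for i in sorted(idx)]
        for seq, score in cands:
            rows.append((f"seed{si}", seq, d, "ml", float(score)))
    return pd.DataFrame(rows, columns=["seed_id", "sequence", "edit_distance",
                                       "provenance", "score"])


def write_pool_fasta(pool: pd.DataFrame, path: str) -> None:
    """Write a mutant pool as FASTA with ids seedid_distance_serial."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(row.sequence),
                  id=f"{row.seed_id}_{row.edit_distance}_{i:06d}",
                  description=row.provenance)
        for i, row in enumerate(pool.itertuples(index=False))
    ]
    SeqIO.write(records, path, "fasta")
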