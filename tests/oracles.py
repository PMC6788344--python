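"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities with plain loops or explicit
enumeration, deliberately sharing no code with the implementation under
test (only the model's weight arrays are read).
"""

from __future__ import annotations

import numpy as np


# ---- naive network forward ---------------------------------------------------


def naive_conv3d(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Direct 'same'-padded cross-correlation; x is (C, D, H, W)."""
    f, c, k, _, _ = W.shape
    _, d, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    out = np.zeros((f, d, h, w))
    for i in range(k):
        for j in range(k):
            for l in range(k):
                patch = xp[:, i : i + d, j : j + h, l : l + w]
                out += np.einsum("fc,cdhw->fdhw", W[:, :, i, j, l], patch)
    return out + b[:, None, None, None]


def naive_maxpool(x: np.ndarray, size: int = 2):
    """Window max pool with explicit loops; returns output and argmax indices."""
    c, d, h, w = x.shape
    dd, hh, ww = -(-d // size), -(-h // size), -(-w // size)
    out = np.full((c, dd, hh, ww), -np.inf)
    arg = np.zeros((c, dd, hh, ww, 3), dtype=int)
    for ci in range(c):
        for a in range(dd):
            for bb in range(hh):
                for cc in range(ww):
                    best = -np.inf
                    for da in range(size):
                        for db in range(size):
                            for dc in range(size):
                                i, j, l = a * size + da, bb * size + db, cc * size + dc
                                if i < d and j < h and l < w and x[ci, i, j, l] > best:
                                    best = x[ci, i, j, l]
                                    arg[ci, a, bb, cc] = (i, j, l)
                    out[ci, a, bb, cc] = best
    return out, arg


def _stab(z: np.ndarray, eps: float) -> np.ndarray:
    return z + eps * np.where(z >= 0, 1.0, -1.0)


def naive_relevance(model, x1: np.ndarray, x2: np.ndarray, eps: float, target: int = 1):
    """Explicit layer-by-layer epsilon-rule redistribution for one pair.

    Reimplements the whole forward pass with loops, records every
    intermediate tensor, and redistributes the target logit backward with
    explicit receptive-field sums.  Returns (map1, map2, target_score).
    """
    x1 = np.asarray(x1, dtype=np.float64)[None] if x1.ndim == 3 else x1
    x2 = np.asarray(x2, dtype=np.float64)[None] if x2.ndim == 3 else x2

    def module_forward(mod, x):
        state = {"x": x, "branches": []}
        acts = []
        for conv in mod.convs:
            z = naive_conv3d(x, conv.W.astype(np.float64), conv.b.astype(np.float64))
            a = np.maximum(z, 0.0)
            state["branches"].append({"z": z, "a": a, "conv": conv})
            acts.append(a)
        cat = np.concatenate(acts, axis=0)
        pooled, arg = naive_maxpool(cat, mod.pool.size)
        state["cat"] = cat
        state["arg"] = arg
        state["out"] = pooled
        return state

    def branch_forward(x):
        states = []
        cur = x
        for mod in model.branch:
            st = module_forward(mod, cur)
            states.append(st)
            cur = st["out"]
        return states, cur

    sa, a = branch_forward(np.asarray(x1[0], dtype=np.float64)[None])
    sb, b = branch_forward(np.asarray(x2[0], dtype=np.float64)[None])
    sign = np.sign(a - b)
    m = np.abs(a - b)
    post_states = []
    cur = m
    for mod in model.post:
        st = module_forward(mod, cur)
        post_states.append(st)
        cur = st["out"]
    c = cur.shape[0]
    flatarg = []
    pooled = np.zeros(c)
    for ci in range(c):
        idx = np.unravel_index(np.argmax(cur[ci]), cur[ci].shape)
        flatarg.append(idx)
        pooled[ci] = cur[ci][idx]
    W = model.head.W.astype(np.float64)
    bb = model.head.b.astype(np.float64)
    z_out = W @ pooled + bb
    score = z_out[target]

    # backward redistribution
    R_out = np.zeros_like(z_out)
    R_out[target] = z_out[target]
    R_pooled = np.zeros_like(pooled)
    for j in range(len(z_out)):
        if R_out[j] == 0:
            continue
        s = R_out[j] / _stab(z_out[j], eps)
        R_pooled += pooled * W[j] * s
    R_cur = np.zeros_like(cur)
    for ci in range(c):
        R_cur[ci][flatarg[ci]] = R_pooled[ci]

    def module_backward(mod, st, R):
        # unpool winner-take-all
        R_cat = np.zeros_like(st["cat"])
        cc, dd, hh, ww = R.shape
        for ci in range(cc):
            for a_ in range(dd):
                for b_ in range(hh):
                    for c_ in range(ww):
                        i, j, l = st["arg"][ci, a_, b_, c_]
                        R_cat[ci, i, j, l] += R[ci, a_, b_, c_]
        # split channels, relu pass-through, conv redistribution
        x = st["x"]
        R_x = np.zeros_like(x)
        off = 0
        for br in st["branches"]:
            f = br["z"].shape[0]
            R_a = R_cat[off : off + f]
            off += f
            s = R_a / _stab(br["z"], eps)
            conv = br["conv"]
            Wc = conv.W.astype(np.float64)
            k = conv.kernel
            p = k // 2
            c_in, d, h, w = x.shape
            sp = np.pad(s, ((0, 0), (p, p), (p, p), (p, p)))
            back = np.zeros_like(x)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        # input voxel v feeds output v + p - (i,j,l) offset
                        back += np.einsum(
                            "fc,fdhw->cdhw",
                            Wc[:, :, i, j, l],
                            sp[:, k - 1 - i : k - 1 - i + d, k - 1 - j : k - 1 - j + h,
                               k - 1 - l : k - 1 - l + w],
                        )
            R_x += x * back
        return R_x

    for mod, st in zip(reversed(model.post), reversed(post_states)):
        R_cur = module_backward(mod, st, R_cur)
    # merge: local linearization sign(d)*a - sign(d)*b
    s = R_cur / _stab(m, eps)
    R_a = s * (sign * a)
    R_b = s * (-sign * b)
    for mod, st in zip(reversed(model.branch), reversed(sa)):
        R_a = module_backward(mod, st, R_a)
    for mod, st in zip(reversed(model.branch), reversed(sb)):
        R_b = module_backward(mod, st, R_b)
    return R_a[0], R_b[0], float(score)


# ---- statistics oracles ------------------------------------------------------


def pair_count_auc(scores, labels) -> float:
    """Mann-Whitney AUC by explicit pair enumeration, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_min_corner_cutoff(scores, labels):
    """Brute-force search over all 'score >= t' rules for the min-corner point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    candidates = sorted(set(scores)) + [np.inf]
    best = None
    for t in candidates:
        pred = scores >= t
        sens = np.mean(pred[labels == 1])
        spec = np.mean(~pred[labels == 0])
        dist = np.sqrt((1 - sens) ** 2 + (1 - spec) ** 2)
        if best is None or dist < best[0] - 1e-15:
            best = (dist, t, sens, spec)
    return best[1], best[2], best[3]


def permutation_delong_p(scores_a, scores_b, labels, n_draws=10000, seed=0):
    """Paired permutation test: randomly swap the two models' scores per subject."""
    rng = np.random.default_rng(seed)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)

    def rank_auc(s):
        from scipy.stats import rankdata

        r = rankdata(s)
        n1 = (y == 1).sum()
        n0 = (y == 0).sum()
        return (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    observed = abs(rank_auc(sa) - rank_auc(sb))
    count = 0
    n = len(y)
    for _ in range(n_draws):
        flip = rng.integers(0, 2, size=n).astype(bool)
        pa = np.where(flip, sb, sa)
        pb = np.where(flip, sa, sb)
        if abs(rank_auc(pa) - rank_auc(pb)) >= observed - 1e-12:
            count += 1
    return count / n_draws
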