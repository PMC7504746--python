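"""Numba-compiled inner training loop for the word2vec-style trainer.

Single-threaded on purpose: determinism of the draw sequence (subsampling,
dynamic window widths, negative samples) is part of the training contract.
The arithmetic per example mirrors ``embedding.example_loss_and_grads``.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _draw_negative(cdf: np.ndarray) -> int:
    u = np.random.random()
    return int(np.searchsorted(cdf, u))


@njit(cache=True)
def train(
    tokens: np.ndarray,       # int32 flat corpus
    sent_starts: np.ndarray,  # int64 sentence offsets, len = n_sentences + 1
    w_in: np.ndarray,         # float32 (V, dim), updated in place
    w_out: np.ndarray,        # float32 (V, dim), updated in place
    noise_cdf: np.ndarray,    # float64 cumulative unigram^0.75
    keep_prob: np.ndarray,    # float64 subsampling keep probabilities
    window: int,
    negative: int,
    cbow: bool,
    epochs: int,
    initial_lr: float,
    final_lr: float,
    seed: int,
) -> None:
    np.random.seed(seed)
    dim = w_in.shape[1]
    n_tokens = tokens.shape[0]
    total = float(epochs * n_tokens)
    processed = 0

    kept = np.empty(n_tokens, dtype=np.int32)
    h = np.empty(dim, dtype=np.float32)
    grad_h = np.empty(dim, dtype=np.float32)

    for _epoch in range(epochs):
        for s in range(sent_starts.shape[0] - 1):
            lo, hi = sent_starts[s], sent_starts[s + 1]
            # frequent-word subsampling
            m = 0
            for j in range(lo, hi):
                w = tokens[j]
                if keep_prob[w] >= 1.0 or np.random.random() < keep_prob[w]:
                    kept[m] = w
                    m += 1
            processed += hi - lo
            if m < 2:
                continue
            progress = processed / total
            lr = initial_lr + (final_lr - initial_lr) * progress
            if lr < final_lr:
                lr = final_lr

            for i in range(m):
                center = kept[i]
                b = np.random.randint(1, window + 1)
                c0 = i - b if i - b > 0 else 0
                c1 = i + b + 1 if i + b + 1 < m else m
                n_ctx = c1 - c0 - 1
                if n_ctx <= 0:
                    continue

                if cbow:
                    # h = mean of context input vectors
                    for d in range(dim):
                        h[d] = 0.0
                        grad_h[d] = 0.0
                    for j in range(c0, c1):
                        if j == i:
                            continue
                        row = kept[j]
                        for d in range(dim):
                            h[d] += w_in[row, d]
                    for d in range(dim):
                        h[d] /= n_ctx
                    # positive target = center, then negatives
                    for t_i in range(negative + 1):
                        if t_i == 0:
                            target = center
                            label = 1.0
                        else:
                            target = _draw_negative(noise_cdf)
                            if target == center:
                                continue
                            label = 0.0
                        score = 0.0
                        for d in range(dim):
                            score += w_out[target, d] * h[d]
                        f = 1.0 / (1.0 + np.exp(-score))
                        g = (f - label) * lr
                        for d in range(dim):
                            grad_h[d] += g * w_out[target, d]
                            w_out[target, d] -= g * h[d]
                    for j in range(c0, c1):
                        if j == i:
                            continue
                        row = kept[j]
                        for d in range(dim):
                            w_in[row, d] -= grad_h[d] / n_ctx
                else:
                    # skip-gram: each context token is a positive output
                    for j in range(c0, c1):
                        if j == i:
                            continue
                        ctx_word = kept[j]
                        for d in range(dim):
                            grad_h[d] = 0.0
                        for t_i in range(negative + 1):
                            if t_i == 0:
                                target = ctx_word
                                label = 1.0
                            else:
                                target = _draw_negative(noise_cdf)
                                if target == ctx_word:
                                    continue
                                label = 0.0
                            score = 0.0
                            for d in range(dim):
                                score += w_out[target, d] * w_in[center, d]
                            f = 1.0 / (1.0 + np.exp(-score))
                            g = (f - label) * lr
                            for d in range(dim):
                                grad_h[d] += g * w_out[target, d]
                            for d in range(dim):
                                w_out[target, d] -= g * w_in[center, d]
                        for d in range(dim):
                            w_in[center, d] -= grad_h[d]
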