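"""Numba kernels for the collapsed Gibbs LDA sampler.

Token-level collapsed Gibbs over topic assignments z with symmetric
Dirichlet priors alpha (document-topic) and eta (topic-word). Point
estimates are posterior means of the Rao-Blackwellised theta/phi over
post-burn-in sweeps. Seeded via numba's np.random state, so runs are
deterministic for a given seed.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_lda(doc_ids, word_ids, K, V, D, alpha, eta, n_iter, burn_in, seed,
              store_z):
    np.random.seed(seed)
    N = doc_ids.shape[0]
    z = np.empty(N, np.int64)
    ndk = np.zeros((D, K), np.int64)
    nkw = np.zeros((K, V), np.int64)
    nk = np.zeros(K, np.int64)
    nd = np.zeros(D, np.int64)
    for i in range(N):
        k = np.random.randint(0, K)
        z[i] = k
        ndk[doc_ids[i], k] += 1
        nkw[k, word_ids[i]] += 1
        nk[k] += 1
        nd[doc_ids[i]] += 1

    doc_acc = np.zeros((D, K))
    word_acc = np.zeros((K, V))
    ll = np.zeros(n_iter)
    n_keep = n_iter - burn_in
    if store_z:
        z_samples = np.zeros((n_keep, N), np.int8)
    else:
        z_samples = np.zeros((1, 1), np.int8)

    p = np.empty(K)
    for it in range(n_iter):
        for i in range(N):
            d = doc_ids[i]
            w = word_ids[i]
            k = z[i]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            tot = 0.0
            for kk in range(K):
                p[kk] = (ndk[d, kk] + alpha) * (nkw[kk, w] + eta) / (nk[kk] + V * eta)
                tot += p[kk]
            u = np.random.random() * tot
            acc = 0.0
            k_new = K - 1
            for kk in range(K):
                acc += p[kk]
                if u < acc:
                    k_new = kk
                    break
            z[i] = k_new
            ndk[d, k_new] += 1
            nkw[k_new, w] += 1
            nk[k_new] += 1

        # observed-data log-likelihood proxy under the current state
        s = 0.0
        for i in range(N):
            d = doc_ids[i]
            w = word_ids[i]
            pi = 0.0
            for kk in range(K):
                theta = (ndk[d, kk] + alpha) / (nd[d] + K * alpha)
                phi = (nkw[kk, w] + eta) / (nk[kk] + V * eta)
                pi += theta * phi
            s += np.log(pi)
        ll[it] = s

        if it >= burn_in:
            j = it - burn_in
            for d in range(D):
                for kk in range(K):
                    doc_acc[d, kk] += (ndk[d, kk] + alpha) / (nd[d] + K * alpha)
            for kk in range(K):
                for w in range(V):
                    word_acc[kk, w] += (nkw[kk, w] + eta) / (nk[kk] + V * eta)
            if store_z:
                for i in range(N):
                    z_samples[j, i] = z[i]

    return doc_acc / n_keep, word_acc / n_keep, ll, z_samples


@njit(cache=True)
def gibbs_fold_in(doc_ids, word_ids, phi, D, alpha, n_iter, burn_in, seed):
    """Gibbs over new-document assignments with topic_word (phi) held fixed."""
    np.random.seed(seed)
    K = phi.shape[0]
    N = doc_ids.shape[0]
    z = np.empty(N, np.int64)
    ndk = np.zeros((D, K), np.int64)
    nd = np.zeros(D, np.int64)
    for i in range(N):
        k = np.random.randint(0, K)
        z[i] = k
        ndk[doc_ids[i], k] += 1
        nd[doc_ids[i]] += 1

    doc_acc = np.zeros((D, K))
    n_keep = n_iter - burn_in
    p = np.empty(K)
    for it in range(n_iter):
        for i in range(N):
            d = doc_ids[i]
            w = word_ids[i]
            k = z[i]
            ndk[d, k] -= 1
            tot = 0.0
            for kk in range(K):
                p[kk] = (ndk[d, kk] + alpha) * phi[kk, w]
                tot += p[kk]
            u = np.random.random() * tot
            acc = 0.0
            k_new = K - 1
            for kk in range(K):
                acc += p[kk]
                if u < acc:
                    k_new = kk
                    break
            z[i] = k_new
            ndk[d, k_new] += 1
        if it >= burn_in:
            for d in range(D):
                for kk in range(K):
                    doc_acc[d, kk] += (ndk[d, kk] + alpha) / (nd[d] + K * alpha)

    return doc_acc / n_keep
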