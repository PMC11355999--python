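import numpy as np
import pytest

import metabopanel as mp


@pytest.fixture
def config():
    return mp.RunConfig(rng_seed=1)


@pytest.fixture
def default_design():
    return mp.SimDesign()


@pytest.fixture
def null_design():
    """No planted effects, no drift: every metabolite is null."""
    return mp.SimDesign(n_planted={}, drift_amplitude=0.0)


@pytest.fixture
def strong_design():
    """Small feature space with strong planted effects (|log2 FC| >= 1)."""
    return mp.SimDesign(
        n_metabolites=24,
        n_planted={"ControlFlx:Control": 3, "CSIS:Control": 3,
                   "CSISFlx:CSIS": 3},
        fc_down_range=(0.3, 0.5),
        fc_up_range=(2.0, 3.3),
    )


@pytest.fixture
def simulated(default_design):
    table, truth = mp.simulate_peak_table(default_design, seed=7)
    behavior = mp.simulate_behavior(default_design, table, truth, seed=7)
    return table, truth, behavior


def prepare_log(table, config=None):
    """raw -> qc_normalized -> tss -> log, returning (tss, log) tables."""
    cfg = config or mp.RunConfig()
    if table.role_mask("qc_pooled").sum() >= 2:
        table, report = mp.qc_normalize(table)
        table = mp.qc_filter(table, report, cfg)
    t = mp.tss(table)
    return t, mp.log_transform(t)


# ---- independent oracles (never call the code paths they check) ----------

def brute_force_bh(p):
    """Direct min-over-tails Benjamini-Hochberg definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for rank_i in range(m):
        q = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_i, m)), 1.0)
        q_sorted[rank_i] = q
    out = np.empty(m)
    out[order] = q_sorted
    return out


def pair_counting_auc(pos, neg):
    """AUC as Mann-Whitney pair counting, ties worth one half."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_greedy(X, y, plans, max_steps, c_reg=1.0):
    """Plain-loop sequential forward scorer sharing the fold plan."""
    from sklearn.svm import SVC
    m = X.shape[1]
    selected, path = [], []
    for _ in range(max_steps):
        best_j, best_acc = None, -1.0
        for j in range(m):
            if j in selected:
                continue
            cols = selected + [j]
            correct = total = 0
            for plan in plans:
                for tr, te in plan:
                    mu = X[tr][:, cols].mean(axis=0)
                    sd = X[tr][:, cols].std(axis=0)
                    sd[sd == 0] = 1.0
                    clf = SVC(kernel="linear", C=c_reg)
                    clf.fit((X[tr][:, cols] - mu) / sd, y[tr])
                    pred = clf.predict((X[te][:, cols] - mu) / sd)
                    correct += int((pred == y[te]).sum())
                    total += len(te)
            acc = correct / total
            if acc > best_acc:
                best_j, best_acc = j, acc
        selected.append(best_j)
        path.append((best_j, best_acc))
    return path
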