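"""Contrastive module: analytic loss values, brute-force oracles, geometry."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from sonovis.contrast import (ContrastConfig, EmbeddingBatch, ProjectionHead,
                              build_pairs, loss_infonce, loss_margin,
                              loss_total, project_joint)
from sonovis.nn.tensor import Tensor


def unit_rows(a):
    a = np.asarray(a, dtype=float)
    return a / np.linalg.norm(a, axis=1, keepdims=True)


def make_batch(z, labels, top_k=None, similar_to=None):
    return build_pairs(Tensor(np.asarray(z, dtype=float)), labels,
                       similar_to=similar_to, top_k=top_k)


def infonce_bruteforce(z, labels, tau):
    """Scalar double-loop oracle for the standard contrastive loss."""
    z = np.asarray(z)
    sims = z @ z.T
    terms = []
    for i in range(len(labels)):
        negs = [j for j in range(len(labels)) if labels[j] != labels[i]]
        for p in range(len(labels)):
            if p == i or labels[p] != labels[i]:
                continue
            num = np.exp(sims[i, p] / tau)
            den = num + sum(np.exp(sims[i, j] / tau) for j in negs)
            terms.append(-np.log(num / den))
    return np.mean(terms)


@pytest.fixture
def cfg():
    return ContrastConfig()


class TestProjection:
    def test_joint_embedding_is_unit_norm(self, cfg):
        rng = np.random.default_rng(0)
        head = ProjectionHead(16, cfg, rng)
        zv = Tensor(rng.normal(size=(6, 16)).astype(np.float32))
        za = Tensor(rng.normal(size=(6, 16)).astype(np.float32))
        _, _, zm = project_joint(zv, za, head)
        np.testing.assert_allclose(np.linalg.norm(zm.data, axis=1), 1.0,
                                   atol=1e-6)

    def test_equal_modalities_collapse_to_one_embedding(self, cfg):
        rng = np.random.default_rng(1)
        head = ProjectionHead(16, cfg, rng)
        x = Tensor(rng.normal(size=(4, 16)).astype(np.float32))
        zv, za, zm = project_joint(x, x, head)
        np.testing.assert_allclose(zm.data, zv.data, atol=1e-6)

    def test_zero_head_raises_on_degenerate_norm(self, cfg):
        rng = np.random.default_rng(2)
        head = ProjectionHead(16, cfg, rng)
        for p in head.parameters():
            p.data[...] = 0.0
        x = Tensor(np.ones((2, 16), np.float32))
        with pytest.raises(ValueError):
            project_joint(x, x, head)


class TestBuildPairs:
    def test_label_partition(self):
        z = unit_rows(np.random.default_rng(0).normal(size=(4, 8)))
        batch = make_batch(z, [0, 0, 1, 1])
        assert batch.positives[0] == [1]
        assert set(batch.negatives[0]) <= {2, 3}

    def test_unlimited_k_keeps_all_negatives(self):
        z = unit_rows(np.random.default_rng(1).normal(size=(6, 8)))
        batch = make_batch(z, [0, 0, 1, 1, 2, 2])
        assert sorted(batch.negatives[0]) == [2, 3, 4, 5]

    def test_designated_lookalike_always_kept(self):
        rng = np.random.default_rng(2)
        # class 1 embeddings made maximally dissimilar to class 0 so ranking
        # alone would drop them at small k
        z = np.vstack([unit_rows(rng.normal(size=(2, 8))),
                       -unit_rows(rng.normal(size=(1, 8))),
                       unit_rows(rng.normal(size=(3, 8)))])
        labels = [0, 0, 1, 2, 2, 2]
        batch = make_batch(unit_rows(z), labels, top_k=1, similar_to={0: 1})
        for anchor in (0, 1):
            assert any(labels[j] == 1 for j in batch.negatives[anchor])

    def test_single_class_batch_rejected(self):
        z = unit_rows(np.random.default_rng(3).normal(size=(3, 4)))
        with pytest.raises(ValueError):
            make_batch(z, [1, 1, 1])

    def test_negatives_ranked_by_similarity(self):
        z = unit_rows(np.random.default_rng(4).normal(size=(5, 8)))
        batch = make_batch(z, [0, 0, 1, 1, 1])
        sims = batch.similarity
        for i in range(2):
            ranked = batch.negatives[i]
            assert all(sims[i, ranked[j]] >= sims[i, ranked[j + 1]]
                       for j in range(len(ranked) - 1))


class TestInfoNCE:
    def test_equal_similarities_one_negative_gives_ln2(self, cfg):
        z = np.tile(unit_rows([[1.0, 0.0]]), (3, 1))   # all identical
        batch = make_batch(z, [0, 0, 1])
        loss = loss_infonce(batch, cfg)
        assert loss.item() == pytest.approx(np.log(2.0), abs=1e-9)

    @pytest.mark.parametrize("n_neg", [2, 5, 9])
    def test_equal_similarities_generalise_to_ln_n_plus_one(self, cfg, n_neg):
        labels = [0, 0] + list(range(1, n_neg + 1))
        z = np.tile(unit_rows([[0.6, 0.8]]), (len(labels), 1))
        batch = make_batch(z, labels)
        # restrict to the two class-0 anchors: each sees 1 pos + n_neg negs
        batch = EmbeddingBatch(batch.zm, batch.labels, batch.similarity,
                               [batch.positives[0], batch.positives[1]] +
                               [[] for _ in range(n_neg)],
                               batch.negatives)
        loss = loss_infonce(batch, cfg)
        assert loss.item() == pytest.approx(np.log(n_neg + 1.0), abs=1e-9)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        z = unit_rows(rng.normal(size=(8, 4)))
        labels = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        cfg = ContrastConfig(temperature=0.5)
        batch = make_batch(z, labels)
        got = loss_infonce(batch, cfg).item()
        want = infonce_bruteforce(z, labels, 0.5)
        assert got == pytest.approx(want, abs=1e-6)

    def test_rotation_invariance(self):
        """Cosine similarity is preserved by any global orthogonal rotation."""
        rng = np.random.default_rng(6)
        z = unit_rows(rng.normal(size=(6, 5)))
        labels = [0, 0, 1, 1, 2, 2]
        cfg = ContrastConfig(temperature=0.2)
        q = ortho_group.rvs(5, random_state=7)
        a = loss_infonce(make_batch(z, labels), cfg).item()
        b = loss_infonce(make_batch(z @ q, labels), cfg).item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_verbatim_mode_differs_from_default(self):
        rng = np.random.default_rng(7)
        z = unit_rows(rng.normal(size=(6, 4)))
        labels = [0, 0, 1, 1, 2, 2]
        cfg = ContrastConfig()
        batch = make_batch(z, labels)
        assert loss_infonce(batch, cfg).item() != \
            pytest.approx(loss_infonce(batch, cfg, verbatim=True).item())


class TestMargin:
    def test_satisfied_margin_is_zero(self):
        cfg = ContrastConfig(margin=0.2)
        # positives identical to anchors, negatives orthogonal:
        # d_pos^2 = 0, d_neg^2 = 2 > delta
        z = unit_rows([[1, 0], [1, 0], [0, 1], [0, 1]])
        batch = make_batch(z, [0, 0, 1, 1])
        assert loss_margin(batch, cfg).item() == 0.0

    def test_collapsed_embeddings_give_delta(self):
        cfg = ContrastConfig(margin=0.35)
        z = np.tile(unit_rows([[1.0, 0.0]]), (4, 1))
        batch = make_batch(z, [0, 0, 1, 1])
        assert loss_margin(batch, cfg).item() == pytest.approx(0.35, abs=1e-7)

    def test_verbatim_variant_rewards_wrong_geometry(self):
        """The printed-sign variant penalises exactly the configuration the
        default form accepts (positives at the anchor, negatives far away)."""
        cfg = ContrastConfig(margin=0.2)
        z = unit_rows([[1, 0], [1, 0], [0, 1], [0, 1]])
        batch = make_batch(z, [0, 0, 1, 1])
        assert loss_margin(batch, cfg).item() == 0.0
        # d_pos = 0, d_neg = 2 -> printed form gives delta + 2
        assert loss_margin(batch, cfg, verbatim=True).item() == pytest.approx(2.2)

    def test_matches_bruteforce_triplet_oracle(self):
        rng = np.random.default_rng(8)
        z = unit_rows(rng.normal(size=(7, 4)))
        labels = np.array([0, 0, 0, 1, 1, 2, 2])
        cfg = ContrastConfig(margin=0.2)
        batch = make_batch(z, labels)
        terms = []
        for i in range(7):
            for p in range(7):
                if p == i or labels[p] != labels[i]:
                    continue
                for ng in range(7):
                    if labels[ng] == labels[i]:
                        continue
                    dp = np.sum((z[i] - z[p]) ** 2)
                    dn = np.sum((z[i] - z[ng]) ** 2)
                    terms.append(max(0.0, 0.2 + dp - dn))
        assert loss_margin(batch, cfg).item() == pytest.approx(np.mean(terms),
                                                               abs=1e-6)


class TestTotal:
    def test_zero_weights_reduce_to_classification(self):
        cfg = ContrastConfig(lambda_contrast=0.0, lambda_margin=0.0)
        total = loss_total(Tensor(1.7), Tensor(2.0), Tensor(3.0), cfg)
        assert total.item() == pytest.approx(1.7)

    def test_weighted_sum_arithmetic(self):
        cfg = ContrastConfig(lambda_contrast=0.5, lambda_margin=0.1)
        total = loss_total(Tensor(1.0), Tensor(2.0), Tensor(3.0), cfg)
        assert total.item() == pytest.approx(2.3)

    def test_gradient_is_weighted_sum_of_component_gradients(self):
        """Finite-difference check of d L_total / d embeddings."""
        rng = np.random.default_rng(9)
        cfg = ContrastConfig(lambda_contrast=0.5, lambda_margin=0.1)
        raw = rng.normal(size=(4, 3))
        labels = [0, 0, 1, 1]

        def total_of(arr):
            from sonovis.nn import functional as F
            zm = F.l2_normalize(Tensor(arr, requires_grad=True), axis=-1)
            batch = build_pairs(zm, labels)
            batch = EmbeddingBatch(zm, batch.labels, batch.similarity,
                                   batch.positives, batch.negatives)
            return loss_total(Tensor(0.0), loss_infonce(batch, cfg),
                              loss_margin(batch, cfg), cfg)

        t = Tensor(raw.copy(), requires_grad=True)
        from sonovis.nn import functional as F
        zm = F.l2_normalize(t, axis=-1)
        batch = build_pairs(zm, labels)
        batch = EmbeddingBatch(zm, batch.labels, batch.similarity,
                               batch.positives, batch.negatives)
        loss = loss_total(Tensor(0.0), loss_infonce(batch, cfg),
                          loss_margin(batch, cfg), cfg)
        loss.backward()
        eps = 1e-6
        for (i, j) in [(0, 0), (1, 2), (3, 1)]:
            up = raw.copy()
            up[i, j] += eps
            down = raw.copy()
            down[i, j] -= eps
            num = (total_of(up).item() - total_of(down).item()) / (2 * eps)
            assert t.grad[i, j] == pytest.approx(num, abs=1e-4)

    def test_nan_component_aborts(self):
        cfg = ContrastConfig()
        with pytest.raises(FloatingPointError):
            loss_total(Tensor(np.nan), Tensor(0.0), Tensor(0.0), cfg)


def test_gradient_descent_separates_classes():
    """Minimising L_cs + L_margin pulls classes apart: final intra-class
    distance is below inter-class distance."""
    from sonovis.nn import functional as F
    from sonovis.nn.optim import AdamW
    rng = np.random.default_rng(10)
    cfg = ContrastConfig(temperature=0.2, margin=0.5)
    raw = Tensor(rng.normal(size=(8, 6), scale=0.1), requires_grad=True)
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    opt = AdamW([raw], lr=0.05, weight_decay=0.0)
    for _ in range(120):
        opt.zero_grad()
        zm = F.l2_normalize(raw, axis=-1)
        pairs = build_pairs(zm, labels)
        batch = EmbeddingBatch(zm, pairs.labels, pairs.similarity,
                               pairs.positives, pairs.negatives)
        (loss_infonce(batch, cfg) + loss_margin(batch, cfg)).backward()
        opt.step()
    z = raw.data / np.linalg.norm(raw.data, axis=1, keepdims=True)
    d = ((z[:, None] - z[None]) ** 2).sum(-1)
    same = labels[:, None] == labels[None]
    np.fill_diagonal(same, False)
    intra = d[same].mean()
    inter = d[~same & (d > -1)].mean()
    assert intra < inter
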