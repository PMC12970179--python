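import numpy as np
import pytest

from mvmol import nn
from mvmol.chem_io import parse_and_canonicalize
from mvmol.encoders import (
    EncoderConfig,
    GraphEncoder,
    ImageEncoder,
    TextEncoder,
    extract_attention,
    load_checkpoint,
    save_checkpoint,
)
from mvmol.views import (
    ImageView,
    build_vocabulary,
    featurize_graph,
    laplacian_pe,
    render_image,
    tokenize_smiles,
)

SMALL = dict(embed_dim=16, depth=2, heads=2, output_dim=24)


@pytest.fixture(scope="module")
def graph_encoder():
    return GraphEncoder(EncoderConfig("graph", seed=3, **SMALL))


@pytest.fixture(scope="module")
def vocab(small_library):
    return build_vocabulary([r.canonical_smiles for r in small_library.records])


@pytest.fixture(scope="module")
def text_encoder(vocab):
    return TextEncoder(EncoderConfig("text", seed=3, **SMALL), vocab)


@pytest.fixture(scope="module")
def image_encoder():
    return ImageEncoder(EncoderConfig("image", embed_dim=4, depth=1, heads=1, output_dim=24, seed=3))


class TestConfig:
    def test_full_scale_default_widths(self):
        assert EncoderConfig("graph").embed_dim == 512
        assert EncoderConfig("text").embed_dim == 768

    def test_positive_dims_enforced(self):
        with pytest.raises(ValueError):
            EncoderConfig("graph", depth=0)


class TestGraphEncoder:
    def test_output_shape_and_determinism(self, graph_encoder, aspirin):
        view = laplacian_pe(featurize_graph(aspirin), k=8)
        a = graph_encoder.encode(view)
        b = graph_encoder.encode(view)
        assert a.z.shape == (24,)
        assert np.array_equal(a.z, b.z)

    def test_requires_laplacian_pe(self, graph_encoder, aspirin):
        with pytest.raises(ValueError, match="laplacian"):
            graph_encoder.encode(featurize_graph(aspirin))

    def test_pooled_embedding_invariant_to_token_permutation(self, graph_encoder):
        """Mean pooling is symmetric: permuting atoms (with their PE rows)
        leaves the pooled embedding unchanged up to numerics."""
        a = parse_and_canonicalize("CCOc1ccccc1")
        b = parse_and_canonicalize("c1ccccc1OCC")  # same molecule, new atom order
        za = graph_encoder.encode(laplacian_pe(featurize_graph(a), 8)).z
        zb = graph_encoder.encode(laplacian_pe(featurize_graph(b), 8)).z
        assert np.allclose(za, zb, atol=1e-5)

    def test_one_step_descent(self, aspirin):
        enc = GraphEncoder(EncoderConfig("graph", seed=0, **SMALL))
        batch = GraphEncoder.prepare([laplacian_pe(featurize_graph(aspirin), 8)])
        opt = nn.Adam(enc.parameters(), lr=1e-3)
        losses = []
        for _ in range(2):
            loss = (enc(batch) ** 2).sum()
            losses.append(loss.data.item())
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert losses[1] < losses[0]


class TestTextEncoder:
    def test_output_shape(self, text_encoder, vocab, aspirin):
        view = tokenize_smiles(aspirin.canonical_smiles, vocab)
        assert text_encoder.encode(view).z.shape == (24,)

    def test_padding_invariance(self, text_encoder, vocab):
        views = [tokenize_smiles("CCO", vocab), tokenize_smiles("CC(=O)Oc1ccccc1C(=O)O", vocab)]
        single = text_encoder(text_encoder.prepare([views[0]])).data[0]
        batched = text_encoder(text_encoder.prepare(views)).data[0]
        assert np.allclose(single, batched, atol=1e-10)

    def test_out_of_range_ids_rejected(self, text_encoder):
        batch = {"ids": np.array([[10**6]]), "mask": np.ones((1, 1))}
        with pytest.raises(ValueError, match="vocabulary"):
            text_encoder(batch)


class TestImageEncoder:
    def test_wrong_size_rejected(self, image_encoder):
        bad = ImageView(pixels=np.zeros((100, 100, 3)), mode="eval")
        with pytest.raises(ValueError, match="224"):
            image_encoder.encode(bad)

    def test_all_zero_image_finite(self, image_encoder):
        view = ImageView(pixels=np.zeros((224, 224, 3)), mode="eval")
        z = image_encoder.encode(view).z
        assert z.shape == (24,) and np.all(np.isfinite(z))

    def test_small_translation_bounded_change(self, image_encoder, aspirin):
        """A 2 px shift of the depiction moves the embedding by a bounded
        amount relative to its own norm (average-pool stem smooths it)."""
        raw = render_image(aspirin, mode="eval").pixels
        shifted = np.roll(raw, 2, axis=1)
        z0 = image_encoder.encode(ImageView(raw, "eval")).z
        z1 = image_encoder.encode(ImageView(shifted, "eval")).z
        assert np.linalg.norm(z1 - z0) < 0.5 * np.linalg.norm(z0)


class TestAttention:
    def test_graph_attention_normalized(self, graph_encoder, aspirin):
        view = laplacian_pe(featurize_graph(aspirin), 8)
        emb = graph_encoder.encode(view, record_attention=True)
        w = extract_attention(emb)
        assert len(w) >= view.n_tokens
        assert np.all(w >= 0) and abs(w.sum() - 1.0) < 1e-6

    def test_single_token_gets_full_weight(self, graph_encoder):
        view = laplacian_pe(featurize_graph(parse_and_canonicalize("C")), 8)
        w = extract_attention(graph_encoder.encode(view, record_attention=True))
        assert abs(w[0] - 1.0) < 1e-9

    def test_image_saliency_normalized(self, image_encoder, benzene):
        emb = image_encoder.encode(render_image(benzene, "eval"), record_attention=True)
        w = extract_attention(emb)
        assert np.all(w >= 0) and abs(w.sum() - 1.0) < 1e-6

    def test_extraction_without_recording_fails(self, graph_encoder, benzene):
        emb = graph_encoder.encode(laplacian_pe(featurize_graph(benzene), 8))
        with pytest.raises(RuntimeError, match="recording"):
            extract_attention(emb)


class TestCheckpoint:
    def test_round_trip_reproduces_embedding(self, tmp_path, vocab, aspirin):
        enc = TextEncoder(EncoderConfig("text", seed=8, **SMALL), vocab)
        view = tokenize_smiles(aspirin.canonical_smiles, vocab)
        before = enc.encode(view).z
        path = tmp_path / "enc.npz"
        save_checkpoint(enc, path)
        loaded = load_checkpoint(path, vocab)
        assert np.array_equal(loaded.encode(view).z, before)
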