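"""Observation tagger: gold projection, decoding, training."""

import numpy as np
import pytest

from fhx import tagger
from fhx.model import ObservationAnnotation
from fhx.preprocess import segment


def project(doc, strings):
    gold = {ObservationAnnotation(s) for s in strings}
    return tagger.project_gold_tags(doc, gold)


class TestGoldProjection:
    def test_multiword_span_receives_b_i_tags(self):
        doc = segment("d", "The family history is significant for mental "
                           "retardation, birth defects and asthma.")
        (_, tags), = project(doc, ["mental retardation"])
        surfaces = [t.surface for t in doc.sentences()[0].tokens]
        i = surfaces.index("mental")
        assert tags[i] == "B-Observation"
        assert tags[i + 1] == "I-Observation"
        assert all(t == "O" for j, t in enumerate(tags)
                   if j not in (i, i + 1))

    def test_empty_gold_gives_all_o(self, doc):
        for _, tags in project(doc, []):
            assert set(tags) <= {"O"}

    def test_all_occurrences_are_tagged(self):
        doc = segment("d", "Her mother has cancer. Her aunt also has cancer.")
        projected = project(doc, ["cancer"])
        n_b = sum(tags.count("B-Observation") for _, tags in projected)
        assert n_b == 2

    def test_missing_gold_string_logs_warning(self, caplog):
        doc = segment("d", "Her mother is healthy.")
        with caplog.at_level("WARNING"):
            project(doc, ["stomach cancer"])
        assert "stomach cancer" in caplog.text

    def test_longest_gold_wins_on_overlap(self):
        doc = segment("d", "She has diabetes type 2.")
        (_, tags), = project(doc, ["diabetes", "diabetes type 2"])
        assert tags == ["O", "O", "B-Observation", "I-Observation",
                        "I-Observation", "O"]

    def test_projection_decode_round_trip(self):
        """BIO-decoding projected tags recovers exactly the gold strings
        that occur in the text."""
        doc = segment(
            "d", "Her mother has diabetes type 2 and high cholesterol.\n\n"
                 "Her maternal aunt has asthma. Her father is healthy.")
        present = {"diabetes type 2", "high cholesterol", "asthma"}
        projected = project(doc, present | {"never in text"})
        recovered = set()
        for sent, tags in projected:
            for i, j in tagger.spans_from_tags(tags):
                recovered.add(doc.text[sent.tokens[i].start:
                                       sent.tokens[j - 1].end].lower())
        assert recovered == present


class TestDecodeAndDictionary:
    def test_bio_codec_spans(self):
        tags = ["B-Observation", "I-Observation", "O", "B-Observation"]
        assert tagger.spans_from_tags(tags) == [(0, 2), (3, 4)]

    def test_untrained_model_decodes_empty(self, doc):
        assert tagger.decode_observations(doc, tagger.CrfModel()) == set()

    def test_duplicate_spans_collapse(self):
        doc = segment("d", "Her mother has asthma. Her father has asthma.")
        model = _memorizing_model(["asthma"])
        assert tagger.decode_observations(doc, model) == \
            {ObservationAnnotation("asthma")}

    def test_dictionary_longest_match(self):
        doc = segment("d", "The patient's mother has diabetes type 2 and "
                           "heart disease.")
        out = tagger.dictionary_tagger(
            doc, {"diabetes", "diabetes type 2", "disease", "heart disease"})
        assert out == {ObservationAnnotation("diabetes type 2"),
                       ObservationAnnotation("heart disease")}

    def test_dictionary_empty_lexicon_rejected(self, doc):
        with pytest.raises(ValueError):
            tagger.dictionary_tagger(doc, set())


def _memorizing_model(words):
    """Model whose word-identity weights tag exactly `words` as B."""
    model = tagger.CrfModel()
    for w in words:
        model.encoder.weights[f"w={w.lower()}"] = np.array([0.0, 10.0, 0.0])
    return model


def _toy_corpus(rng, n=60):
    """Linearly separable sentences: disease words in fixed positive
    contexts, distractor sentences without diseases."""
    diseases = ["asthma", "lupus", "anemia", "gout", "migraines", "eczema"]
    rels = ["mother", "father", "sister", "brother"]
    data = []
    for _ in range(n):
        d = diseases[int(rng.integers(len(diseases)))]
        r = rels[int(rng.integers(len(rels)))]
        if rng.random() < 0.75:
            surfaces = ["Her", r, "has", d, "."]
            tags = ["O", "O", "O", "B-Observation", "O"]
        else:
            surfaces = ["Her", r, "is", "healthy", "."]
            tags = ["O"] * 5
        data.append((surfaces, tags))
    return data


class TestTraining:
    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            tagger.train_crf([])

    def test_loglik_nondecreasing_full_batch(self, rng):
        data = _toy_corpus(rng, 50)
        cfg = tagger.TrainConfig(epochs=8, batch_size=50,
                                 learning_rate=0.5, seed=1)
        model = tagger.train_crf(data, config=cfg)
        hist = model.train_loglik_history
        assert all(b >= a - 1e-9 for a, b in zip(hist, hist[1:]))

    def test_training_is_deterministic(self, rng):
        data = _toy_corpus(rng, 30)
        cfg = tagger.TrainConfig(epochs=3, seed=7)
        m1 = tagger.train_crf(data, config=cfg)
        m2 = tagger.train_crf(data, config=cfg)
        np.testing.assert_array_equal(m1.transitions, m2.transitions)
        for f, w in m1.encoder.weights.items():
            np.testing.assert_array_equal(w, m2.encoder.weights[f])

    def test_learnability_on_separable_data(self, rng):
        data = _toy_corpus(rng, 80)
        model = tagger.train_crf(
            data, config=tagger.TrainConfig(epochs=10, seed=0))
        tags = model.decode_tags(["Her", "uncle", "has", "asthma", "."])
        assert tags[3] == "B-Observation"
        assert tags.count("O") == 4

    def test_gradient_matches_finite_differences(self, rng):
        surfaces = ["has", "mild", "asthma"]
        model = tagger.CrfModel()
        feats = set()
        for i in range(3):
            feats.update(model.encoder.features(surfaces, i))
        for f in feats:
            model.encoder.weights[f] = rng.normal(size=3) * 0.1
        model.transitions = rng.normal(size=(3, 3)) * 0.1
        model.start = rng.normal(size=3) * 0.1
        model.stop = rng.normal(size=3) * 0.1
        batch = [(surfaces, ["O", "O", "B-Observation"])]
        _, grads = tagger.loglik_and_grad(model, batch)

        eps = 1e-6
        worst = 0.0

        def fd(get, set_):
            nonlocal worst
            orig = get()
            set_(orig + eps)
            lp = tagger.training_loglik(model, batch)
            set_(orig - eps)
            lm = tagger.training_loglik(model, batch)
            set_(orig)
            return (lp - lm) / (2 * eps)

        for arr, garr in [(model.transitions, grads["transitions"]),
                          (model.start, grads["start"]),
                          (model.stop, grads["stop"])]:
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                num = fd(lambda: arr[idx],
                         lambda v, idx=idx, arr=arr: arr.__setitem__(idx, v))
                worst = max(worst, abs(num - garr[idx]))
        for f in sorted(feats):
            w = model.encoder.weights[f]
            g = grads["features"].get(f, np.zeros(3))
            for j in range(3):
                num = fd(lambda: w[j],
                         lambda v, j=j, w=w: w.__setitem__(j, v))
                worst = max(worst, abs(num - g[j]))
        assert worst < 1e-4

    def test_pretrain_empty_aux_equals_plain_training(self, rng):
        data = _toy_corpus(rng, 30)
        cfg = tagger.TrainConfig(epochs=3, seed=5)
        plain = tagger.train_crf(data, config=cfg)
        via = tagger.pretrain_then_finetune([], data, target_config=cfg)
        np.testing.assert_array_equal(plain.transitions, via.transitions)

    def test_pretrain_aux_equals_target_is_two_rounds(self, rng):
        data = _toy_corpus(rng, 30)
        cfg = tagger.TrainConfig(epochs=3, seed=5)
        two_stage = tagger.pretrain_then_finetune(
            data, data, aux_config=cfg, target_config=cfg)
        manual = tagger.train_crf(data, config=cfg)
        manual = tagger.train_crf(data, config=cfg, model=manual)
        np.testing.assert_array_equal(two_stage.transitions,
                                      manual.transitions)


def test_model_serialization_round_trip(tmp_path, rng):
    data = _toy_corpus(rng, 20)
    model = tagger.train_crf(data, config=tagger.TrainConfig(epochs=2))
    path = tmp_path / "model.json"
    model.save(path)
    loaded = tagger.CrfModel.load(path)
    np.testing.assert_array_equal(model.transitions, loaded.transitions)
    surfaces = ["Her", "mother", "has", "asthma", "."]
    assert model.decode_tags(surfaces) == loaded.decode_tags(surfaces)
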