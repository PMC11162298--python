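import numpy as np
import pytest

from dasv.candidate_regions import Window
from dasv.dual_attention_model import DualAttentionNet, ModelConfig
from dasv.feature_encoding import WindowSample
from dasv.training_and_calling import (CallerParams, DeletionCall,
                                       LabeledDataset, TrainConfig,
                                       build_training_dataset,
                                       call_from_records, label_windows,
                                       read_calls_vcf, read_truth,
                                       read_truth_bed, train, write_vcf)

TINY = ModelConfig(image_channels_per_scale=[4, 8], n_scales=2,
                   seq_embed_dim=8, head_dim=8, dropout=0.0, seed=1)


def _sample(start, chrom="chr1", label=None, seed=0):
    rng = np.random.default_rng(seed + start)
    return WindowSample(
        Window(chrom, start),
        rng.choice([0, 2, 3, 4, 5, 9], size=100).astype(np.int16),
        rng.integers(0, 2, (100, 100, 3)).astype(np.uint8) * 255,
        rng.integers(0, 2, (100, 100, 3)).astype(np.uint8) * 255,
        label)


# ----------------------------------------------------------------- labelling

def test_no_truth_labels_everything_negative():
    ds = label_windows([_sample(0), _sample(50)], truth=[])
    assert ds.labels.tolist() == [0, 0]


@pytest.mark.parametrize("truth,expected", [
    (("chr1", 50, 150), 1),   # overlap 50 >= 25
    (("chr1", 90, 95), 1),    # short truth: overlap 5 >= min(25, 5)
    (("chr1", 95, 300), 0),   # long truth: overlap 5 < 25
    (("chr2", 50, 150), 0),   # other chromosome
])
def test_window_labelling_rule(truth, expected):
    ds = label_windows([_sample(0)], [truth])
    assert ds.labels.tolist() == [expected]


def test_duplicate_windows_dropped():
    ds = label_windows([_sample(0), _sample(0), _sample(50)], [])
    assert len(ds.samples) == 2


# ------------------------------------------------------------------ training

def test_training_requires_both_classes():
    samples = [_sample(i * 50, label=1) for i in range(6)]
    with pytest.raises(ValueError, match="degenerate"):
        train(LabeledDataset(samples), TINY, TrainConfig(epochs=1))


def test_training_smoke_and_descent():
    samples = [_sample(i * 50, label=i % 2, seed=3) for i in range(12)]
    model, metrics = train(LabeledDataset(samples), TINY,
                           TrainConfig(epochs=2, batch=4, seed=0))
    assert len(metrics) >= 1
    assert {"epoch", "train_loss", "val_f1"} <= metrics[0].keys()
    assert np.isfinite(metrics[0]["train_loss"])
    probs = model.predict_proba(samples)
    assert ((probs >= 0) & (probs <= 1)).all()


# ------------------------------------------------------------------- calling

def test_threshold_monotonicity(small_sim, small_records):
    cfg, _res = small_sim
    model = DualAttentionNet(TINY)
    counts = []
    for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
        calls = call_from_records(
            small_records, cfg.ref_length, model,
            CallerParams(p_threshold=thr))
        counts.append(len(calls))
    assert counts == sorted(counts, reverse=True)


def test_calls_partition_clusters(small_sim, small_records):
    cfg, _res = small_sim
    model = DualAttentionNet(TINY)
    calls = call_from_records(small_records, cfg.ref_length, model,
                              CallerParams(p_threshold=0.0))
    for a, b in zip(calls, calls[1:]):
        assert a.end <= b.start or a.chrom != b.chrom


def test_empty_input_returns_no_calls():
    model = DualAttentionNet(TINY)
    assert call_from_records([], 1000, model) == []


# ----------------------------------------------------------------- truth I/O

def test_read_truth_bed_and_malformed_line(tmp_path):
    p = tmp_path / "t.bed"
    p.write_text("chr1\t100\t600\tDEL\thomozygous\n")
    assert read_truth(p) == [("chr1", 100, 600)]
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t100\t600\nchr1\toops\n")
    with pytest.raises(ValueError, match="line 2"):
        read_truth_bed(bad)


# ---------------------------------------------------------------------- VCF

@pytest.fixture()
def reference(tmp_path):
    import pysam
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    path = tmp_path / "ref.fa"
    path.write_text(f">chr1\n{seq}\n")
    pysam.faidx(str(path))
    return path, seq


def test_empty_calls_write_valid_header_only_vcf(tmp_path, reference):
    ref_path, _seq = reference
    out = tmp_path / "empty.vcf"
    write_vcf([], ref_path, out)
    assert read_calls_vcf(out) == []


def test_vcf_coordinate_conversion(tmp_path, reference):
    ref_path, seq = reference
    out = tmp_path / "one.vcf"
    call = DeletionCall("chr1", 1049, 1249, score=0.875, support=12)
    write_vcf([call], ref_path, out)
    line = [l for l in out.read_text().splitlines()
            if not l.startswith("#")][0]
    fields = line.split("\t")
    assert fields[0] == "chr1"
    assert fields[1] == "1049"                 # POS: base before the event
    assert fields[3] == seq[1048].upper()      # REF is that base
    assert fields[4] == "<DEL>"
    info = dict(kv.split("=") for kv in fields[7].split(";"))
    assert info["END"] == "1249"
    assert info["SVLEN"] == "-200"
    assert info["SVTYPE"] == "DEL"
    assert info["SUPPORT"] == "12"


def test_vcf_round_trip(tmp_path, reference):
    ref_path, _seq = reference
    calls = [DeletionCall("chr1", 100, 180, 0.92, 7),
             DeletionCall("chr1", 900, 1500, 1.0, 30)]
    out = tmp_path / "rt.vcf"
    write_vcf(calls, ref_path, out)
    back = read_calls_vcf(out)
    for a, b in zip(calls, back):
        assert (a.chrom, a.start, a.end, a.length) == \
            (b.chrom, b.start, b.end, b.length)
        assert abs(a.score - b.score) < 1e-3
        assert a.support == b.support


def test_vcf_truth_parse_matches_bed(tmp_path, reference):
    ref_path, _seq = reference
    calls = [DeletionCall("chr1", 300, 420, 0.9, 9)]
    vcf_path = tmp_path / "t.vcf"
    write_vcf(calls, ref_path, vcf_path)
    assert read_truth(vcf_path) == [("chr1", 300, 420)]


# ------------------------------------------------------------ dataset builder

def test_training_dataset_has_no_duplicate_windows(small_sim, small_records):
    cfg, res = small_sim
    ds = build_training_dataset(small_records, cfg.ref_length, res.truth,
                                n_background=30, seed=4)
    keys = [(s.window.chrom, s.window.start) for s in ds.samples]
    assert len(keys) == len(set(keys))
    assert ds.n_pos > 0 and ds.n_neg > 0


def test_window_cap_subsamples_large_regions(small_sim, small_records):
    cfg, res = small_sim
    full = build_training_dataset(small_records, cfg.ref_length, res.truth,
                                  n_background=0, seed=4)
    capped = build_training_dataset(small_records, cfg.ref_length, res.truth,
                                    n_background=0,
                                    max_windows_per_region=4, seed=4)
    assert len(capped.samples) <= len(full.samples)
    assert len(capped.samples) <= 4 * len(res.truth) + 5
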