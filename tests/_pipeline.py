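"""Synthetic end-to-end exon study shared by the acceptance suite and the
acceptance report script.

Builds a per-exon mini-genome in which "repressed-like" exons carry a planted
CU-rich tract in the upstream intron and a weak 3' splice site,
"enhanced-like" exons carry a downstream tract, and neutral exons carry
neither; then runs the full feature -> regulation-model pipeline.
"""

from __future__ import annotations

import numpy as np

from splicebind import regulation_model as rm
from splicebind import score_norm as sn
from splicebind import splice_features as sf
from splicebind import triplet_hmm as th
from splicebind.seq_io import GenomicInterval, SequenceRecord

_BASES = np.array(list("ACGU"))

EXON_START, EXON_END = 300, 400
CHROM_LEN = 550


def _draw(rng, n, p):
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _junction(rng, weak: bool) -> str:
    """Last 14 intronic + first exonic base; canonical AG kept in both."""
    if weak:
        tract = _draw(rng, 12, [0.25, 0.25, 0.25, 0.25])
    else:
        tract = _draw(rng, 12, [0.05, 0.45, 0.05, 0.45])  # polypyrimidine
    return tract + "AG" + "G"


def strong_junction_pool(n: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    return [_junction(rng, weak=False) for _ in range(n)]


def build_exon_study(
    hmm_params: th.HmmParameters,
    n_per_group: tuple[int, int, int] = (100, 60, 100),
    seed: int = 0,
):
    """Returns (genome, exons, labels) for repressed-like / enhanced-like /
    neutral synthetic exons on one + strand chromosome each."""
    rng = np.random.default_rng(seed)
    uniform = [0.25, 0.25, 0.25, 0.25]
    cu_rich = [0.0, 0.45, 0.10, 0.45]

    genome: dict[str, SequenceRecord] = {}
    exons: list[GenomicInterval] = []
    labels: list[str] = []
    groups = (
        ("repressed", n_per_group[0], True, True, False),
        ("enhanced", n_per_group[1], False, True, True),
        ("non_regulated", n_per_group[2], False, False, False),
    )
    i = 0
    for label, n, up_tract, weak_ss, down_tract in groups:
        for _ in range(n):
            pad5 = _draw(rng, 50, uniform)
            # upstream intron: 250 nt ending at the exon; the last 15 nt carry
            # the 3'ss junction window
            up_body = _draw(rng, 235, cu_rich if up_tract else uniform)
            junction = _junction(rng, weak=weak_ss)[:15]
            exon_seq = _draw(rng, EXON_END - EXON_START, uniform)
            down_seq = _draw(rng, 100, cu_rich if down_tract else uniform)
            pad3 = _draw(rng, 50, uniform)
            chrom = pad5 + up_body + junction + exon_seq + down_seq + pad3
            assert len(chrom) == CHROM_LEN
            name = f"exon{i}"
            genome[name] = SequenceRecord(name, chrom)
            exons.append(GenomicInterval(name, EXON_START, EXON_END, name, "+"))
            labels.append(label)
            i += 1
    return genome, exons, labels


def run_regulation_pipeline(
    hmm_params: th.HmmParameters,
    genome,
    exons,
    labels,
    ss_matrix_seed: int = 1,
):
    """Features -> screening -> stepwise fit -> p_repressed for every exon."""
    matrix = sf.SpliceSiteMatrix.from_junction_sequences(
        strong_junction_pool(200, ss_matrix_seed), "3ss"
    )
    scored = []
    per_exon_regions = []
    for exon in exons:
        regions = sf.define_regulatory_regions(exon, CHROM_LEN)
        triple = []
        for region, cls in (
            (regions.upstream_intron, "upstream_intron"),
            (regions.exon, "exon"),
            (regions.downstream_intron, "downstream_intron"),
        ):
            from splicebind.seq_io import extract_region_sequence

            seq = extract_region_sequence(genome, region)
            raw = th.log_odds_score(hmm_params, seq)
            scored.append((cls, len(seq), raw))
            triple.append((cls, len(seq), raw))
        per_exon_regions.append(triple)
    _, bin_stats = sn.length_bin_normalize(scored)

    vectors = [
        sf.compute_exon_features(exon, genome, hmm_params, bin_stats, matrix)
        for exon in exons
    ]
    raw = np.array([v.as_array() for v in vectors])
    ref = sf.FeatureStandardizer.from_table(raw)
    X = np.array([v.standardize(ref).as_array() for v in vectors])

    names = ["x1", "x2", "x3", "x4"]
    labels = np.asarray(labels)
    retained = rm.screen_features_ttest(X, labels, names)
    selected, model = rm.stepwise_select(X, labels, retained, names)
    cols = [names.index(f) for f in selected]
    probs = rm.predict_probabilities_batch(model, X[:, cols])
    return {
        "X": X,
        "labels": labels,
        "model": model,
        "selected": selected,
        "p_repressed": probs[:, 0],
    }
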