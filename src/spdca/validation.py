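"""Self-contained synthetic validation studies of the SP-DCA pipeline.

Two seeded studies exercise the full method with known ground truth:

* **Planted-pair recovery** — sample paired alignments from a Potts model
  with five isolated planted inter-protein couplings and score how many
  of the top-5 ranked coupling predictions are planted (precision@5,
  k = number of planted pairs).
* **Hot-spot recovery** — plant one contiguous 7-residue interacting
  peptide pair, run coupling inference plus the Gaussian-kernel
  convolution, and measure the area Jaccard overlap between the top-1
  extracted rectangle and the planted region.

Study conditions (30+30 columns, alphabet size 8, coupling strength 2.0,
2000 sequences) are fixed here; the convolution prior for the hot-spot
study is scaled to the synthetic protein length (a = b = 0.05, half-window
l = 5, i.e. a kernel width comparable to the planted peptide length, the
same width-to-peptide ratio the production defaults imply for full-length
receptors), and the extraction fraction equals the planted-interface
areal fraction so that predicted and planted areas are commensurate.
"""

from __future__ import annotations

import numpy as np

from .coevolution import (
    coupling_scores,
    fit_plm,
    inter_protein_block,
    sequence_weights,
    synthetic_alphabet,
    top_pairs,
)
from .core import PriorParams, convolve, extract_hotspots, rectangle_jaccard
from .synthetic import (
    evaluate_recovery,
    make_interface_model,
    make_planted_model,
    sample_msa,
)


def planted_coupling_precision(
    seeds: list[int],
    len_a: int = 30,
    len_b: int = 30,
    q: int = 8,
    n_pairs: int = 5,
    strength: float = 2.0,
    m: int = 2000,
) -> list[float]:
    """Precision@n_pairs of plmDCA inter-protein coupling ranking, per seed."""
    out = []
    for seed in seeds:
        model, truth = make_planted_model(len_a, len_b, q, n_pairs, strength, seed)
        pa = sample_msa(model, m, seed=seed)
        w = sequence_weights(pa)
        fit = fit_plm(pa, w, alphabet=synthetic_alphabet(q))
        block = inter_protein_block(coupling_scores(fit), len_a, len_b)
        res = evaluate_recovery(top_pairs(block), truth, k=n_pairs)
        out.append(res["precision_at_k"])
    return out


def hotspot_recovery_jaccards(
    seeds: list[int],
    len_a: int = 30,
    len_b: int = 30,
    q: int = 8,
    region_a: tuple[int, int] = (11, 17),
    region_b: tuple[int, int] = (13, 19),
    strength: float = 2.0,
    m: int = 2000,
    params: PriorParams | None = None,
    top_fraction: float | None = None,
) -> list[float]:
    """Top-1 rectangle vs planted region Jaccard overlap, per seed.

    The extraction fraction defaults to the planted-interface areal
    fraction of the map (predicted and planted areas commensurate).
    """
    params = params or PriorParams(a=0.05, b=0.05, l=5)
    width_a = region_a[1] - region_a[0] + 1
    width_b = region_b[1] - region_b[0] + 1
    if top_fraction is None:
        top_fraction = round(width_a * width_b / (len_a * len_b), 2)
    out = []
    for seed in seeds:
        model, truth = make_interface_model(
            len_a, len_b, q, region_a, region_b, strength, seed
        )
        pa = sample_msa(model, m, seed=seed)
        w = sequence_weights(pa)
        fit = fit_plm(pa, w, alphabet=synthetic_alphabet(q))
        block = inter_protein_block(coupling_scores(fit), len_a, len_b)
        conv = convolve(block, params)
        rects = extract_hotspots(conv, top_fraction=top_fraction, min_separation=10)
        out.append(rectangle_jaccard(rects[0], truth.rectangle()) if rects else 0.0)
    return out
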