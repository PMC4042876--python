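"""Generate the synthetic study genome and write all raw inputs.

Produces, under results/simulated/: wiggle coverage tracks for Pol II, the
CTD phospho-isoforms, histone marks, MNase and stranded short RNAs; BED
gene models; FASTA sequence; tag/pair streams; the probe-level expression
atlas; and the planted truth tables every later step is scored against.
"""

import argparse
from pathlib import Path

from ctdseq.synthetic import SimConfig, simulate_to_dir


def run(seed: int = 0, out_dir="results/simulated") -> None:
    cfg = SimConfig(seed=seed)
    simulate_to_dir(cfg, out_dir)
    print(f"simulated {cfg.n_genes} expressed + {cfg.n_silent_genes} silent "
          f"genes, {cfg.n_enhancers} enhancers, {cfg.n_distractors} "
          f"lincRNA-like distractors -> {out_dir}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", default="results/simulated")
    args = ap.parse_args()
    run(args.seed, args.out_dir)
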