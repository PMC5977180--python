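"""Transcriptomic validation: moderated-t differential expression per study,
BH FDR, ROC/AUC, and the cross-study candidate report."""

import argparse
from pathlib import Path

import pandas as pd

from exomewas import expression
from exomewas.pipeline import PipelineConfig, _study_from_frame

parser = argparse.ArgumentParser()
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--out-dir", type=Path, default=Path("results/dge"))
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

candidates = PipelineConfig.default(seed=args.seed).candidates
results = {}
for path in sorted(args.data_dir.glob("expression_*.tsv")):
    name = path.stem.removeprefix("expression_")
    df = pd.read_csv(path, sep="\t", index_col=0)
    rt = expression.differential_expression(_study_from_frame(df, name))
    rt.write(args.out_dir / f"dge_{name}.tsv")
    results[name] = rt.data

rep = expression.candidate_report(results, candidates)
rep.write(args.out_dir / "candidate_report.tsv")
tested = rep.data[rep.data.status == "tested"]
for _, r in tested[tested.significant].iterrows():
    print(f"{r.gene} in {r.study}: {r.direction}-regulated, "
          f"FDR={r.bh_fdr:.2g}, AUC={r.auc:.2f}"
          + ("  [direction discordant across studies]" if r.discordant_direction else ""))
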