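"""Generate the synthetic study: genotype cohort + expression studies.

Emits a VCF with 8 cases against four European-like control panels
(107/107/91/99), two injected risk variants at the discovery effect sizes,
four rare-burden genes, and three two-group expression studies with the
candidate genes differentially expressed.  Everything downstream reads
these files, so the whole analysis is reproducible from `--seed`.
"""

import argparse
from pathlib import Path

from exomewas import simulate
from exomewas.pipeline import PipelineConfig

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results/data"))
args = parser.parse_args()

cfg = PipelineConfig.default(seed=args.seed)
G, labels, ann = simulate.gen_genotypes(cfg.sim)
paths = simulate.write_cohort(G, labels, ann, args.out_dir)
print(f"cohort: {G.n_samples} samples x {G.n_variants} variants -> {paths['vcf']}")

for name, ecfg in cfg.expression_sims.items():
    st = simulate.gen_expression(ecfg, study=name)
    # sample columns carry their group so stage 06 needs no side table
    st.sample_ids = [f"{g}_{i}" for i, g in enumerate(st.group)]
    path = args.out_dir / f"expression_{name}.tsv"
    st.write(path)
    print(f"expression study {name}: {len(st.genes)} genes x {len(st.sample_ids)} samples -> {path}")
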