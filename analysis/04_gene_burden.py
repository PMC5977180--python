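"""DANN-weighted gene burden scan, all-variant and rare strata, with
pseudo-replication against every control panel."""

import argparse
from pathlib import Path

from exomewas import burden
from exomewas.core_io import read_annotation, read_labels, read_vcf

parser = argparse.ArgumentParser()
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--out-dir", type=Path, default=Path("results/burden"))
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

G = read_vcf(args.data_dir / "cohort.vcf")
labels = read_labels(args.data_dir / "labels.tsv")
ann = read_annotation(args.data_dir / "annotation.tsv")

rt = burden.burden_scan(
    G, labels, ann, strata=("all", "rare"), cohorts=labels.cohorts,
    discovery_cohort="IBS", n_perm=999, seed=args.seed + 2,
)
rt.write(args.out_dir / "burden.tsv")

for stratum in ("all", "rare"):
    sub = rt.data[(rt.data.stratum == stratum) & (rt.data.cohort == "IBS")]
    sig = sub[sub.significant_bonferroni].sort_values("p_perm")
    print(f"{stratum} stratum: {len(sig)} significant genes vs discovery panel")
    for _, r in sig.iterrows():
        cohorts_sig = rt.data[
            (rt.data.gene == r.gene) & (rt.data.stratum == stratum)
        ]["significant_bonferroni"].sum()
        print(f"  {r.gene}: {r.n_variants} variants, p={r.p_perm:.2g}, "
              f"significant in {cohorts_sig}/4 panels")
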