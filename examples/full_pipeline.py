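"""Run the complete pipeline on a synthetic study bundle.

Writes a self-contained study (spectra CSV, species records CSV, newick
tree, manifest) to a temporary directory, then runs every stage —
colour loci, reward statistics, phylogenetic signal — and prints where
the report landed and the subset sizes it asserted.
"""

import json
import tempfile
from pathlib import Path

from beehex import CommunitySpec, RunConfig, run_all
from beehex.synth import write_study_bundle

workdir = Path(tempfile.mkdtemp(prefix="beehex_demo_"))
write_study_bundle(workdir / "study", CommunitySpec(seed=3))

config = RunConfig(
    records_csv=str(workdir / "study" / "records.csv"),
    tree_file=str(workdir / "study" / "tree.nwk"),
    n_sim=20_000,
    seed=3,
    outdir=str(workdir / "report"),
)
manifest = run_all(config)

print("report written to", config.outdir)
print("subset sizes:", manifest["subset_n"])
print("phylogenetic signal:",
      json.dumps(manifest["phylo"], indent=2))
print(
    "\nThe report directory holds loci.csv, subset_stats.csv, "
    "contingency.json, phylo_signal.json and manifest.json; re-running "
    "with the same config reproduces it byte for byte."
)
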