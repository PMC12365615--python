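"""Full pipeline on a synthetic quarterly bundle with a planted signal.

Generates four quarters of FAERS-like $-delimited files (with revised case
versions to exercise deduplication), plants a 5x reporting-odds multiplier
on (drug_target, pt_0001), then runs parse -> dedup -> assemble -> flag ->
score -> export and prints the top of the ranked PT signal table.
"""

import tempfile
from pathlib import Path

import pandas as pd
import yaml

from pvsignal import GeneratorConfig, generate, load_config, run_pipeline
from pvsignal.synthetic_data import write_bundles, write_vocabulary_files

cfg = GeneratorConfig(n_reports=5000, seed=42, duplicate_rate=0.1,
                      rate_multipliers={("drug_target", "pt_0001"): 5.0})

with tempfile.TemporaryDirectory() as td:
    td = Path(td)
    bundles, truth = generate(cfg)
    write_bundles(bundles, td / "quarters")
    syn, soc = write_vocabulary_files(cfg, td)
    (td / "run.yaml").write_text(yaml.safe_dump(dict(
        input_dir=str(td / "quarters"), synonym_file=str(syn),
        pt_soc_file=str(soc), output_dir=str(td / "out"))))

    outputs = run_pipeline(load_config(td / "run.yaml"))

    sig = pd.read_csv(outputs["pt_signals"], sep="\t")
    print(sig.head(3).to_string(index=False))
    print()
    print(Path(outputs["run_log"]).read_text().splitlines()[-4])

# The planted pair pt_0001 tops the ranking with an ROR near its true odds
# multiplier of 5 and fires all three screening criteria; background PTs,
# generated identically for cases and non-cases, stay near ROR 1.
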