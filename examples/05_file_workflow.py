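"""The same analysis through TSV files and the command line.

Writes a simulated study to disk in the package's TSV formats, then drives
the `irstab` CLI programmatically: simulate -> compute IR.  Useful as a
template for analysing your own preprocessed (log2) expression matrices.
"""

import json
import subprocess
import sys
import tempfile
from pathlib import Path

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    expr, pheno, out = tmp / "study.tsv", tmp / "study_pheno.tsv", tmp / "ir.json"

    subprocess.run([sys.executable, "-m", "irstab.cli", "simulate",
                    "--n-genes", "800", "--n-samples", "80", "--seed", "7",
                    "--out-expr", expr, "--out-pheno", pheno], check=True)
    subprocess.run([sys.executable, "-m", "irstab.cli", "compute",
                    "--expr", expr, "--pheno", pheno,
                    "--contrast", "group1_vs_2", "--n", "4",
                    "--out", out], check=True)

    payload = json.loads(out.read_text())
    print(json.dumps(payload, indent=2))
    print("\nThe JSON above is what `irstab compute` writes: the IR, the")
    print("fitted weight-decay rate lambda, and the low/high classification.")
    print("A manifest (inputs, parameters, version) sits next to each output.")
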