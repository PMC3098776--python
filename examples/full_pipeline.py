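"""End-to-end run: simulate a record, analyze it, write the report.

Produces the per-record JSON report combining spacer lengths, repeat
census and families, hairpin histogram and coverage, tandem arrays,
promoter hits and gene-order classification.
"""

import json
from pathlib import Path

from fernbz.pipeline import analyze_record
from fernbz.simulate import simulate_region, vandenboschia_like_config

aseq, truth = simulate_region(vandenboschia_like_config(seed=3))
report = analyze_record(aseq)

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = out / "example_report.json"
path.write_text(json.dumps({aseq.seq_id: report}, indent=2, sort_keys=True))

print(f"record {aseq.seq_id}: {report['length']} nt, "
      f"analysis scope {report['analysis_scope']}")
print("trnY-trnE spacer:", report["igs"]["trnY-GUA--trnE-UUC"])
print("gene order:", report["gene_order"]["order"],
      "->", report["gene_order"]["type"], "type")
for arr in report["tandem_arrays"]:
    print(f"tandem: period {arr['period']}, {arr['copy_number']} copies, "
          f"modules {arr['modules']}")
print(f"stem-loops: {report['stemloops']['aaa_hits']} AAA hits, "
      f"{report['stemloops']['aaa_coverage_percent']}% of the spacer")
print(f"full report written to {path}")
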