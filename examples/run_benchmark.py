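"""Generate a small end-to-end benchmark and run both pipeline stages on it.

Writes reference files, amplicon/plasmid FASTQ directories, a tracking
database and a truth table under ./scratch/demo_bench, then annotates and
verifies every record and compares the verdicts with the recorded truth.
"""

from pathlib import Path

import pandas as pd

from igkit.annotate import annotate_record
from igkit.compare import compare_record
from igkit.config import Config
from igkit.fixtures import make_benchmark
from igkit.reference import load_constants, load_germline_db, load_primer_table
from igkit.seqio import match_reads_to_records, read_database, read_sequence_file

root = Path("scratch/demo_bench")
bench = make_benchmark(root, n_pairs=12, seed=7)
print(f"benchmark written to {root} ({len(bench.truth)} pairs)")

cfg = Config()
db = load_germline_db(bench.paths["germline"])
constants = load_constants(bench.paths["constants"])
primers = load_primer_table(bench.paths["primers"])
records, _ = read_database(bench.paths["database"])
amp_map, _ = match_reads_to_records(bench.paths["amplicons"], cfg.seqio.filename_regex)
pla_map, _ = match_reads_to_records(bench.paths["plasmids"], cfg.seqio.filename_regex)

truth = bench.truth.set_index("mab_id")
n_verdicts_correct = 0
for record in records:
    amp = {c: read_sequence_file(p)[0] for (m, c), p in amp_map.items() if m == record.mab_id}
    pla = {c: read_sequence_file(p)[0] for (m, c), p in pla_map.items() if m == record.mab_id}
    annotate_record(record, amp, db, constants, primers, cfg)
    reports = compare_record(record, amp, pla, db, cfg)
    expected = truth.loc[record.mab_id, "expected_verdict"]
    got = record.verdict_color
    n_verdicts_correct += got == expected
    chain = truth.loc[record.mab_id, "chain"]
    print(f"{record.mab_id} {chain:6s} verdict={got:5s} expected={expected:5s} "
          f"shm={record.metadata.get(chain + '_shm', '?')}")

print(f"\n{n_verdicts_correct}/{len(records)} verdicts match the generator truth")
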