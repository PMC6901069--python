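"""Smart restart: only a failed step and its downstream cone re-run.

A three-step chain is forced to fail in the middle; resuming skips the
completed upstream step, and editing a parameter afterwards invalidates
exactly that step's downstream cone.
"""

import tempfile
from pathlib import Path

from tagcascade.runner import Step, StepGraph, execute


def make_graph(qc_threshold=27):
    g = StepGraph()
    g.add(Step("qc", lambda p: f"filtered at Q{p['min_avg_q']}",
               params={"min_avg_q": qc_threshold}))
    g.add(Step("cluster", lambda p: "clustered", dependencies=["qc"]))
    g.add(Step("classify", lambda p: "classified", dependencies=["cluster"]))
    return g


state = Path(tempfile.mkdtemp()) / "state"

r1 = execute(make_graph(), state, fail_on={"cluster"})
print("forced failure :", f"executed={r1.executed} failed={r1.failed} blocked={r1.blocked}")

r2 = execute(make_graph(), state, resume=True)
print("resume         :", f"skipped={r2.skipped} executed={r2.executed}")

r3 = execute(make_graph(qc_threshold=30), state, resume=True)
print("param edit     :", f"skipped={r3.skipped} executed={r3.executed}")
print()
print("After the edit nothing is skipped: the qc fingerprint changed, and")
print("fingerprints chain through dependencies, so the whole cone re-ran.")
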