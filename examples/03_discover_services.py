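"""Discover services by predicate and by consumable data type.

The registry indexes each service under the predicates it can attach
(including declared superproperties) and can answer "which services could
run on an individual of this class?" via requirement-coverage matching —
here, a blood-chemistry time-course feeds the generic regression service
because the ontology declares it a specialized kind of X-Y coordinate data.
"""

import owlflow.demo_domain as dd
from owlflow.rdf_core import evaluate_sparql
from owlflow.registry import Registry, export_registry_graph
from owlflow.service_model import SVC_ATTACHES

ont = dd.demo_ontology()
reg = Registry(ontology=ont)
for s in dd.demo_services():
    reg.register(s)

print("who can attach latestBUN?")
for s in reg.find_by_predicate(dd.LATEST_BUN):
    print(f"  {s.iri.value}")

print("who can attach some latestMeasurement (superproperty)?")
for s in reg.find_by_predicate(dd.LATEST_MEASUREMENT):
    print(f"  {s.iri.value}")

print("who can consume a BloodChemistryTimeCourse?")
for s in reg.find_consuming(dd.BLOOD_CHEMISTRY_TIME_COURSE):
    print(f"  {s.iri.value}")

# the same discovery works with plain SPARQL over the exported index
g = export_registry_graph(reg)
rows = evaluate_sparql(
    g, f"SELECT ?s WHERE {{ ?s <{SVC_ATTACHES.value}> <{dd.LATEST_CREATININE.value}> }}"
)
print(f"SPARQL over the exported registry graph ({len(g)} triples) finds "
      f"{len(rows)} service(s) attaching latestCreatinine")
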