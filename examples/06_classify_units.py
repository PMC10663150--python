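"""Classify how migration shaped each unit's population trajectory.

Impact classes compare the realized population change with the
counterfactual without migration (natural change only): does migration
amplify growth or decline, slow it, or reverse its sign?  Direction
classes read the sign pattern of urban vs rural net migration.
"""

from gridmig import (
    ImpactInputs,
    PipelineConfig,
    WorldConfig,
    direction_class,
    impact_class,
)
from gridmig.classify import class_population_shares
from gridmig.pipeline import Pipeline

print("single-unit illustrations:")
for pc, mgr in ((150.0, 50.0), (20.0, 100.0), (-20.0, -100.0), (80.0, 0.0)):
    cls = impact_class(ImpactInputs(pop_change=pc, net_mgr_sum=mgr))
    print(f"  Δpop {pc:+7.0f}, Σmigration {mgr:+7.0f} → {cls.value}")
print(f"  urban +300, rural −120 → {direction_class(300, -120).value}")

pipe = Pipeline(PipelineConfig(
    world=WorldConfig(grid_height=32, grid_width=32, n_countries=4,
                      units_per_country=4, subunits_per_unit=2,
                      years=tuple(range(2000, 2010)), seed=9),
    write_outputs=False,
))
pipe.run()

classified = pipe.artifacts["classification"][1]  # admin-1
print(f"\nadmin-1 units classified: {len(classified)}")
print("\npopulation share by impact class (%):")
print(class_population_shares(classified).round(1).to_string())
print("\npopulation share by direction class (%):")
print(class_population_shares(classified, "direction").round(1).to_string())
# Shares sum to 100% of the classified population; 'zero' direction means
# one of the urban/rural strata has exactly zero cumulative migration.
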