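"""Project SSP2-style population/GDP paths and recompute average incomes.

Income is always GDP over population — aggregates sum their children first,
they never average incomes.
"""

import agrifoodsim as afs
from agrifoodsim.geography import AFR, WLD
from agrifoodsim.macro import average_income, region_trajectory, trajectories_from_world

world = afs.build_world(seed=1)
trajs = trajectories_from_world(world)

africa = region_trajectory(world, AFR, trajs)
world_t = region_trajectory(world, WLD, trajs)

print("Average annual income (thousand USD/person):")
for year in (2010, 2020, 2030):
    print(f"  {year}: Africa {average_income(africa, year):5.1f}   "
          f"World {average_income(world_t, year):5.1f}")

# Africa roughly doubles from ~2.7 to ~5.0 thousand USD/person by 2030;
# compounding 2.8 trillion at 5.2 %/yr for 20 years gives the ~7.7 trillion
# GDP behind that:
print(f"Africa GDP 2030: {afs.project_series(2.8, 0.052, 20)[-1]:.2f} trillion")
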