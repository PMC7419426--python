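{
  "schema_version": "1",
  "description": "Registry of Common Silica Processes (CSPs): task + material + tool triples for the construction sector. Editable; the tool accepts additional CSPs as data accumulate.",
  "csps": [
    {"csp_id": "asphalt_cutting_walk_behind_saw", "material": "asphalt", "task": "cutting", "tool": "walk-behind saw", "label": "Cutting asphalt with walk-behind saw"},
    {"csp_id": "asphalt_milling_milling_machine", "material": "asphalt", "task": "milling", "tool": "milling machine", "label": "Milling asphalt with milling machine"},
    {"csp_id": "cmu_cutting_table_saw", "material": "concrete masonry unit", "task": "cutting", "tool": "table saw", "label": "Cutting concrete masonry units with table saw"},
    {"csp_id": "cmu_cutting_portable_saw", "material": "concrete masonry unit", "task": "cutting", "tool": "powered portable saw", "label": "Cutting concrete masonry units with powered portable saw"},
    {"csp_id": "concrete_cutting_saw", "material": "concrete", "task": "cutting", "tool": "saw", "label": "Cutting concrete with saw"},
    {"csp_id": "concrete_coring_coring_machine", "material": "concrete", "task": "coring", "tool": "coring machine", "label": "Coring concrete with coring machine"},
    {"csp_id": "concrete_drilling_hammer_drill", "material": "concrete", "task": "drilling", "tool": "electric hammer drill", "label": "Drilling concrete with electric hammer drill"},
    {"csp_id": "concrete_grinding_hand_grinder", "material": "concrete", "task": "grinding", "tool": "angle, surface, right angle, or flat grinder", "label": "Grinding concrete with angle, surface, right angle, or flat grinder"},
    {"csp_id": "concrete_grinding_ceiling_grinder", "material": "concrete", "task": "grinding", "tool": "counterbalanced ceiling grinder", "label": "Grinding concrete with counterbalanced ceiling grinder"},
    {"csp_id": "concrete_scarifying", "material": "concrete", "task": "scarifying or bush hammering", "tool": "scarifier or bush hammer", "label": "Scarifying or bush hammering concrete"},
    {"csp_id": "concrete_loading_mixer_truck", "material": "concrete", "task": "loading", "tool": "concrete mixer truck", "label": "Loading concrete mixer truck"},
    {"csp_id": "concrete_breaking_jackhammer", "material": "concrete", "task": "breaking", "tool": "jackhammer", "label": "Breaking concrete with jackhammer"},
    {"csp_id": "shotcrete_spraying", "material": "shot-crete", "task": "spraying", "tool": "compressed air mixture", "label": "Spraying shot-crete with compressed air mixture"},
    {"csp_id": "ceramic_tile_cutting_tile_saw", "material": "ceramic tiles", "task": "cutting", "tool": "portable powered tile saw", "label": "Cutting ceramic tiles with portable powered tile saw"},
    {"csp_id": "earth_moving_heavy_equipment", "material": "rock/sand/earth", "task": "mechanized moving", "tool": "heavy equipment", "label": "Mechanized moving of rock/sand/earth with heavy equipment"},
    {"csp_id": "earth_moving_manual", "material": "rock/sand/earth", "task": "manual moving", "tool": "hand tools", "label": "Manual moving of rock/sand/earth"},
    {"csp_id": "rock_crushing_crusher", "material": "rock/sand/earth", "task": "crushing and processing", "tool": "stationary or mobile crusher", "label": "Crushing and processing rock/sand/earth with a stationary or mobile crusher"},
    {"csp_id": "marble_granite_cutting_saw", "material": "marble/granite", "task": "cutting", "tool": "powered saw", "label": "Cutting marble and/or granite with a powered saw"},
    {"csp_id": "cement_mixing_pouring", "material": "cementicious material", "task": "mixing and pouring", "tool": "mixer", "label": "Mixing and pouring cementicious material"},
    {"csp_id": "drywall_cutting_saw", "material": "drywall", "task": "cutting", "tool": "saw", "label": "Cutting drywall with a saw"},
    {"csp_id": "drywall_grinding_sander", "material": "drywall", "task": "grinding", "tool": "sander or grinder", "label": "Grinding drywall with a sander or grinder"},
    {"csp_id": "mortar_tuck_point_grinding", "material": "mortar", "task": "tuck point grinding", "tool": "grinder", "label": "Tuck point grinding"},
    {"csp_id": "fiber_cement_cutting_portable_saw", "material": "fiber cement board", "task": "cutting", "tool": "portable saw", "label": "Cutting fiber cement board with a portable saw"},
    {"csp_id": "demolition_rock_concrete", "material": "various", "task": "demolition", "tool": "various", "label": "Demolition of rock or concrete structures"},
    {"csp_id": "sweeping_construction_dust", "material": "various", "task": "manual sweeping", "tool": "broom", "label": "Manual sweeping of rock or concrete construction dust"}
  ]
}
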