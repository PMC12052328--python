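{
  "name": "Nova-Conhecimento",
  "scale": {"min": 1, "max": 10},
  "items": [
    {"item_id": "banana_fresh", "label": "Fresh banana", "category": "banana", "nova_group": "G1"},
    {"item_id": "banana_sweet", "label": "Banana sweet with added sugar", "category": "banana", "nova_group": "G3"},
    {"item_id": "banana_cereal_bar", "label": "Banana-flavored cereal bar", "category": "banana", "nova_group": "G4"},
    {"item_id": "beef_fresh", "label": "Fresh beef", "category": "beef", "nova_group": "G1"},
    {"item_id": "beef_dried", "label": "Dried beef with added salt", "category": "beef", "nova_group": "G3"},
    {"item_id": "beef_meatballs", "label": "Frozen beef meatballs", "category": "beef", "nova_group": "G4"},
    {"item_id": "corn_cob", "label": "Fresh corn on the cob", "category": "corn", "nova_group": "G1"},
    {"item_id": "corn_canned", "label": "Canned corn", "category": "corn", "nova_group": "G3"},
    {"item_id": "corn_bread", "label": "Corn-flavored sliced bread", "category": "corn", "nova_group": "G4"},
    {"item_id": "milk_whole", "label": "Pasteurized whole cow's milk", "category": "dairy", "nova_group": "G1"},
    {"item_id": "minas_cheese", "label": "Minas cheese", "category": "dairy", "nova_group": "G3"},
    {"item_id": "dairy_beverage", "label": "Strawberry-flavored dairy beverage", "category": "dairy", "nova_group": "G4"}
  ]
}
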