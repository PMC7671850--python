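"""Load the smoking-reasons taxonomy fixtures and take a census.

Prints the category count and valence breakdown of the full (final) taxonomy
and of the 10-category seed taxonomy the training campaign starts from, then
grows the seed taxonomy by one user-proposed category.
"""

from mibot import add_category, load_full_taxonomy, load_seed_taxonomy, valence_census

full = load_full_taxonomy()
seed = load_seed_taxonomy()

n_pro, n_con, n_both = valence_census(full)
print(f"full taxonomy: {len(full)} categories "
      f"({n_pro} pro-only, {n_con} con-only, {n_both} both)")
print("pro-only:", ", ".join(c.display_name for c in full.categories
                             if c.valence == "pro"))
print(f"seed taxonomy: {len(seed)} categories, all present in the full set:",
      set(seed.ids()) <= set(full.ids()))

result = add_category(
    seed, "Flavor", "both",
    {"pro": ["I get it, the {phrase} is something you enjoy"],
     "con": ["I hear you, the {phrase} it leaves bothers you"]},
)
print(f"after adding 'Flavor': {len(result.taxonomy)} categories "
      f"(version {result.taxonomy.version})")

# adding it again merges instead of duplicating
again = add_category(result.taxonomy, "flavor", "both",
                     {"pro": ["x"], "con": ["y"]})
print(f"adding 'flavor' again: merged={again.merged}, "
      f"still {len(again.taxonomy)} categories")
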