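We kindly request your expertise in analyzing the following microbial metagenomic samples from their metadata texts:

1. Please deduce the source category for the sample, choosing from "animal" (including humans), "plant," "water," "soil," or "other." Your choices are "animal" (incl. human), "plant," "water," "soil," and "other." Give strictly a concise, single-word label for the sample ID.
2. Please infer geographical location where the sample was collected, including the country (NOT the coordinates).
3. Extract strictly 5–8 keywords descriptive of the sample origin, separated by commas. Put them within curly brackets.
4. We seek a brief, up to 3-word description of the sample's specific origin. For "animal" or "plant" sources, please specify the host and part thereof. For "water" samples, the type of water body is sought (e.g., lake, brine, sea, wastewater, etc.). If from "soil," specify (e.g., agricultural, desert, forest, etc.). If from "other" specify which (e.g., urban, laboratory, feed/food, fungus, air, etc.).

If information is missing, kindly indicate "NA." Please separate all values with 3 underscores ("___").

An example response: SRS123456___animal___Los Angeles, USA___{medical, bone fracture, infection, collagen, hospital, intensive care, cast, Staphylococcus epidermidis}___human elbow
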