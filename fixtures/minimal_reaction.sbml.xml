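<?xml version='1.0' encoding='UTF-8'?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" xmlns:layout="http://www.sbml.org/sbml/level3/version1/layout/version1" xmlns:render="http://www.sbml.org/sbml/level3/version1/render/version1" xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance" xmlns:sbd="https://sbdiagram.dev/ns/sbml-extras" level="3" version="1" layout:required="false">
  <model id="model">
    <listOfCompartments>
      <compartment id="c0" name="cell" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="a" name="A" compartment="c0" sboTerm="SBO:0000245" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="b" name="B" compartment="c0" sboTerm="SBO:0000245" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="r0" reversible="false" fast="false" sboTerm="SBO:0000176">
        <listOfReactants>
          <speciesReference species="a" constant="true" sboTerm="SBO:0000010"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="b" constant="true" sboTerm="SBO:0000011"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
    <layout:listOfLayouts>
      <layout:layout layout:id="layout_0">
        <layout:dimensions layout:width="320" layout:height="70"/>
        <layout:listOfSpeciesGlyphs>
          <layout:speciesGlyph layout:id="g_a" layout:species="a">
            <layout:boundingBox>
              <layout:position layout:x="20" layout:y="20"/>
              <layout:dimensions layout:width="100" layout:height="50"/>
            </layout:boundingBox>
          </layout:speciesGlyph>
          <layout:speciesGlyph layout:id="g_b" layout:species="b">
            <layout:boundingBox>
              <layout:position layout:x="220" layout:y="20"/>
              <layout:dimensions layout:width="100" layout:height="50"/>
            </layout:boundingBox>
          </layout:speciesGlyph>
        </layout:listOfSpeciesGlyphs>
        <layout:listOfReactionGlyphs>
          <layout:reactionGlyph layout:id="g_r0" layout:reaction="r0">
            <layout:curve>
              <layout:listOfCurveSegments>
                <layout:curveSegment xsi:type="LineSegment">
                  <layout:start layout:x="70" layout:y="45"/>
                  <layout:end layout:x="270" layout:y="45"/>
                </layout:curveSegment>
              </layout:listOfCurveSegments>
            </layout:curve>
            <layout:listOfSpeciesReferenceGlyphs>
              <layout:speciesReferenceGlyph layout:id="g_r0_srg_0" layout:speciesGlyph="g_a" layout:role="substrate"/>
              <layout:speciesReferenceGlyph layout:id="g_r0_srg_1" layout:speciesGlyph="g_b" layout:role="product"/>
            </layout:listOfSpeciesReferenceGlyphs>
          </layout:reactionGlyph>
        </layout:listOfReactionGlyphs>
        <layout:listOfTextGlyphs>
          <layout:textGlyph layout:id="g_a_label" layout:text="A" layout:graphicalObject="g_a">
            <layout:boundingBox>
              <layout:position layout:x="20" layout:y="20"/>
              <layout:dimensions layout:width="100" layout:height="50"/>
            </layout:boundingBox>
          </layout:textGlyph>
          <layout:textGlyph layout:id="g_b_label" layout:text="B" layout:graphicalObject="g_b">
            <layout:boundingBox>
              <layout:position layout:x="220" layout:y="20"/>
              <layout:dimensions layout:width="100" layout:height="50"/>
            </layout:boundingBox>
          </layout:textGlyph>
        </layout:listOfTextGlyphs>
      </layout:layout>
    </layout:listOfLayouts>
  </model>
</sbml>
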