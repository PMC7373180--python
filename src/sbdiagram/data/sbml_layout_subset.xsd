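<?xml version="1.0" encoding="UTF-8"?>
<!--
  Subset schema for the SBML Level 3 layout package (version 1): layouts
  with compartment/species/reaction/text glyphs, bounding boxes, curves with
  line and cubic-bezier segments, and species-reference glyphs.  Local
  render information (render namespace) may appear inside a layout.
  A leading annotation element (core namespace) carries the auxiliary
  containment/clone/style markers and is skipped.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:layout="http://www.sbml.org/sbml/level3/version1/layout/version1"
           xmlns:render="http://www.sbml.org/sbml/level3/version1/render/version1"
           targetNamespace="http://www.sbml.org/sbml/level3/version1/layout/version1"
           elementFormDefault="qualified"
           attributeFormDefault="qualified">

  <xs:import namespace="http://www.sbml.org/sbml/level3/version1/render/version1"
             schemaLocation="sbml_render_subset.xsd"/>

  <xs:complexType name="Point">
    <xs:attribute name="x" type="xs:double" use="required"/>
    <xs:attribute name="y" type="xs:double" use="required"/>
    <xs:attribute name="z" type="xs:double"/>
  </xs:complexType>

  <xs:complexType name="Dimensions">
    <xs:attribute name="width" type="xs:double" use="required"/>
    <xs:attribute name="height" type="xs:double" use="required"/>
    <xs:attribute name="depth" type="xs:double"/>
  </xs:complexType>

  <xs:complexType name="BoundingBox">
    <xs:sequence>
      <xs:element name="position" type="layout:Point"/>
      <xs:element name="dimensions" type="layout:Dimensions"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:string"/>
  </xs:complexType>

  <xs:complexType name="CurveSegment">
    <xs:sequence>
      <xs:element name="start" type="layout:Point"/>
      <xs:element name="end" type="layout:Point"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="CubicBezierSegment">
    <xs:complexContent>
      <xs:extension base="layout:CurveSegment">
        <xs:sequence>
          <xs:element name="basePoint1" type="layout:Point"/>
          <xs:element name="basePoint2" type="layout:Point"/>
        </xs:sequence>
      </xs:extension>
    </xs:complexContent>
  </xs:complexType>

  <!-- globals so the cubic-bezier derived type (core namespace, to match
       the conventional unprefixed xsi:type values) can reference them -->
  <xs:element name="basePoint1" type="layout:Point"/>
  <xs:element name="basePoint2" type="layout:Point"/>

  <xs:complexType name="Curve">
    <xs:sequence>
      <xs:element name="listOfCurveSegments">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="curveSegment" type="layout:CurveSegment"
                        maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="CompartmentGlyph">
    <xs:sequence>
      <xs:any namespace="##other" processContents="skip" minOccurs="0"/>
      <xs:element name="boundingBox" type="layout:BoundingBox"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="compartment" type="xs:string"/>
    <xs:attribute name="order" type="xs:double"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="SpeciesGlyph">
    <xs:sequence>
      <xs:any namespace="##other" processContents="skip" minOccurs="0"/>
      <xs:element name="boundingBox" type="layout:BoundingBox"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="species" type="xs:string"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="SpeciesReferenceGlyph">
    <xs:sequence>
      <xs:any namespace="##other" processContents="skip" minOccurs="0"/>
      <xs:element name="curve" type="layout:Curve" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="speciesGlyph" type="xs:string"/>
    <xs:attribute name="speciesReference" type="xs:string"/>
    <xs:attribute name="role" type="xs:string"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="ReactionGlyph">
    <xs:sequence>
      <xs:element name="curve" type="layout:Curve" minOccurs="0"/>
      <xs:element name="boundingBox" type="layout:BoundingBox" minOccurs="0"/>
      <xs:element name="listOfSpeciesReferenceGlyphs" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="speciesReferenceGlyph"
                        type="layout:SpeciesReferenceGlyph" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="reaction" type="xs:string"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="TextGlyph">
    <xs:sequence>
      <xs:element name="boundingBox" type="layout:BoundingBox"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="text" type="xs:string"/>
    <xs:attribute name="originOfText" type="xs:string"/>
    <xs:attribute name="graphicalObject" type="xs:string"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="Layout">
    <xs:sequence>
      <xs:element name="dimensions" type="layout:Dimensions"/>
      <xs:element name="listOfCompartmentGlyphs" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="compartmentGlyph" type="layout:CompartmentGlyph"
                        maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="listOfSpeciesGlyphs" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="speciesGlyph" type="layout:SpeciesGlyph"
                        maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="listOfReactionGlyphs" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="reactionGlyph" type="layout:ReactionGlyph"
                        maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="listOfTextGlyphs" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="textGlyph" type="layout:TextGlyph"
                        maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element ref="render:listOfRenderInformation" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="name" type="xs:string"/>
  </xs:complexType>

  <xs:element name="listOfLayouts">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="layout" type="layout:Layout" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

</xs:schema>
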