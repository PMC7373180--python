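<?xml version="1.0" encoding="UTF-8"?>
<!--
  Subset schema for SBGN-ML 0.2 Process Description documents.

  Covers the constructs this library reads and writes: maps, glyphs with
  labels, bounding boxes, state variables, clone markers, ports and nested
  glyphs, and arcs with start/next/end points.  Extension content is
  deliberately left open (the SBGN-ML standard does not define it).
  Element order inside a glyph is relaxed relative to the upstream schema.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:sbgn="http://sbgn.org/libsbgn/0.2"
           targetNamespace="http://sbgn.org/libsbgn/0.2"
           elementFormDefault="qualified"
           attributeFormDefault="unqualified">

  <xs:simpleType name="GlyphClass">
    <xs:restriction base="xs:string">
      <xs:enumeration value="unspecified entity"/>
      <xs:enumeration value="simple chemical"/>
      <xs:enumeration value="macromolecule"/>
      <xs:enumeration value="nucleic acid feature"/>
      <xs:enumeration value="complex"/>
      <xs:enumeration value="complex multimer"/>
      <xs:enumeration value="macromolecule multimer"/>
      <xs:enumeration value="simple chemical multimer"/>
      <xs:enumeration value="nucleic acid feature multimer"/>
      <xs:enumeration value="source and sink"/>
      <xs:enumeration value="perturbing agent"/>
      <xs:enumeration value="phenotype"/>
      <xs:enumeration value="compartment"/>
      <xs:enumeration value="process"/>
      <xs:enumeration value="omitted process"/>
      <xs:enumeration value="uncertain process"/>
      <xs:enumeration value="association"/>
      <xs:enumeration value="dissociation"/>
      <xs:enumeration value="state variable"/>
      <xs:enumeration value="unit of information"/>
      <xs:enumeration value="tag"/>
      <xs:enumeration value="submap"/>
      <xs:enumeration value="terminal"/>
      <xs:enumeration value="and"/>
      <xs:enumeration value="or"/>
      <xs:enumeration value="not"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="ArcClass">
    <xs:restriction base="xs:string">
      <xs:enumeration value="consumption"/>
      <xs:enumeration value="production"/>
      <xs:enumeration value="modulation"/>
      <xs:enumeration value="stimulation"/>
      <xs:enumeration value="catalysis"/>
      <xs:enumeration value="inhibition"/>
      <xs:enumeration value="necessary stimulation"/>
      <xs:enumeration value="logic arc"/>
      <xs:enumeration value="equivalence arc"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="Extension">
    <xs:sequence>
      <xs:any namespace="##any" processContents="skip"
              minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:anyAttribute namespace="##any" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="Bbox">
    <xs:attribute name="x" type="xs:double" use="required"/>
    <xs:attribute name="y" type="xs:double" use="required"/>
    <xs:attribute name="w" type="xs:double" use="required"/>
    <xs:attribute name="h" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="Label">
    <xs:sequence>
      <xs:element name="bbox" type="sbgn:Bbox" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="text" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="State">
    <xs:attribute name="value" type="xs:string"/>
    <xs:attribute name="variable" type="xs:string"/>
  </xs:complexType>

  <xs:complexType name="Point">
    <xs:attribute name="x" type="xs:double" use="required"/>
    <xs:attribute name="y" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="Port">
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="x" type="xs:double" use="required"/>
    <xs:attribute name="y" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="Glyph">
    <xs:sequence>
      <xs:element name="label" type="sbgn:Label" minOccurs="0"/>
      <xs:choice minOccurs="0" maxOccurs="unbounded">
        <xs:element name="state" type="sbgn:State"/>
        <xs:element name="clone" type="sbgn:Extension"/>
        <xs:element name="bbox" type="sbgn:Bbox"/>
        <xs:element name="glyph" type="sbgn:Glyph"/>
        <xs:element name="port" type="sbgn:Port"/>
        <xs:element name="extension" type="sbgn:Extension"/>
      </xs:choice>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="class" type="sbgn:GlyphClass" use="required"/>
    <xs:attribute name="compartmentRef" type="xs:IDREF"/>
    <xs:attribute name="compartmentOrder" type="xs:float"/>
    <xs:attribute name="orientation" type="xs:string"/>
  </xs:complexType>

  <xs:complexType name="Arc">
    <xs:sequence>
      <xs:element name="glyph" type="sbgn:Glyph" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="start" type="sbgn:Point"/>
      <xs:element name="next" type="sbgn:Point" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="end" type="sbgn:Point"/>
      <xs:element name="extension" type="sbgn:Extension" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="class" type="sbgn:ArcClass" use="required"/>
    <xs:attribute name="source" type="xs:IDREF" use="required"/>
    <xs:attribute name="target" type="xs:IDREF" use="required"/>
  </xs:complexType>

  <xs:complexType name="Map">
    <xs:sequence>
      <xs:element name="extension" type="sbgn:Extension" minOccurs="0"/>
      <xs:element name="glyph" type="sbgn:Glyph" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="arc" type="sbgn:Arc" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="language" type="xs:string" use="required"/>
    <xs:attribute name="id" type="xs:ID"/>
  </xs:complexType>

  <xs:element name="sbgn">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="map" type="sbgn:Map" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

</xs:schema>
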